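"""Minimum-jerk instruction trajectories and control-mode scheduling.

In instruction mode the robot guides the wrist along the quintic that
minimizes the integrated squared jerk between rest and target,

    P(tau) = P0 + (PT - P0) * (6 tau^5 - 15 tau^4 + 10 tau^3),
    tau = t / T,

the normative model of smooth human reaching: position interpolates the
endpoints while velocity and acceleration vanish at both. Its jerk cost
(half the integrated squared third derivative) has the closed form
360 A^2 / T^5 for movement amplitude A, and its normalized mean
velocity is 8/15.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import JOINT_RANGE_DEG, ModeSchedule


@dataclass
class TrajectorySpec:
    """Point-to-point movement: start and target in degrees, duration s."""

    start: np.ndarray
    target: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=float)
        self.target = np.asarray(self.target, dtype=float)
        if self.duration <= 0:
            raise ValueError("movement duration must be positive")
        for name, p in (("start", self.start), ("target", self.target)):
            if np.any(np.abs(p) > JOINT_RANGE_DEG):
                raise ValueError(
                    f"{name} {p} outside the +/-{JOINT_RANGE_DEG} deg joint range"
                )


@dataclass
class SampledTrajectory:
    """Uniformly sampled 2-DOF angle series, ``P`` of shape (n, 2) deg."""

    t: np.ndarray
    P: np.ndarray

    @property
    def fs(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])

    @property
    def endpoint(self) -> np.ndarray:
        return self.P[-1]


def minimum_jerk_profile(tau: np.ndarray) -> np.ndarray:
    """The dimensionless quintic 6 tau^5 - 15 tau^4 + 10 tau^3."""
    tau = np.asarray(tau, dtype=float)
    return tau**3 * (6.0 * tau**2 - 15.0 * tau + 10.0)


def minimum_jerk(spec: TrajectorySpec, fs_out: float = 1000.0) -> SampledTrajectory:
    """Sample the minimum-jerk trajectory at ``fs_out`` Hz, endpoints inclusive."""
    n = int(round(spec.duration * fs_out)) + 1
    t = np.arange(n) / fs_out
    t[-1] = spec.duration  # guard rounding so the last sample is exactly T
    tau = t / spec.duration
    shape = minimum_jerk_profile(tau)
    P = spec.start[None, :] + shape[:, None] * (spec.target - spec.start)[None, :]
    return SampledTrajectory(t=t, P=P)


def jerk_cost_closed_form(amplitude: float, duration: float) -> float:
    """Closed-form jerk cost 360 A^2 / T^5 of the minimum-jerk movement."""
    return 360.0 * amplitude**2 / duration**5


def boundary_derivatives(traj: SampledTrajectory) -> dict:
    """Finite-difference velocity and acceleration at both trajectory ends.

    Returns per-end 2-vectors (deg/s, deg/s^2) using one-sided
    second-order stencils; for a generated minimum-jerk trajectory these
    tend to zero as the sampling rate grows.
    """
    P, t = traj.P, traj.t
    if len(t) < 3:
        raise ValueError("need at least three samples")
    h = t[1] - t[0]
    v0 = (-3 * P[0] + 4 * P[1] - P[2]) / (2 * h)
    vT = (3 * P[-1] - 4 * P[-2] + P[-3]) / (2 * h)
    a0 = (P[0] - 2 * P[1] + P[2]) / h**2
    aT = (P[-1] - 2 * P[-2] + P[-3]) / h**2
    return {
        "velocity_start": v0,
        "velocity_end": vT,
        "acceleration_start": a0,
        "acceleration_end": aT,
    }


def instruct(
    class_label: str | int,
    current_position: np.ndarray,
    schedule: ModeSchedule,
    fs_out: float = 1000.0,
) -> SampledTrajectory:
    """Instruction-mode trajectory for a classified movement.

    Generates the minimum-jerk guidance from the current wrist position
    to the target mapped to the decided class, over ``t_instruct``
    seconds. Successive instructions chain: each starts where the
    previous one ended.
    """
    if class_label not in schedule.target_map:
        raise KeyError(f"no target configured for class {class_label!r}")
    spec = TrajectorySpec(
        start=np.asarray(current_position, dtype=float),
        target=np.asarray(schedule.target_map[class_label], dtype=float),
        duration=schedule.t_instruct,
    )
    return minimum_jerk(spec, fs_out)
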