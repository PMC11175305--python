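"""Quantitative pointing-evaluation indices for 2-DOF wrist trajectories.

Accuracy, stability and smoothness of a pointing movement toward a
target are summarized by six indices plus the reaching time:

accuracy
    endpoint error ``e`` — Euclidean distance from target to movement
    endpoint; maximum lateral deviation ``e_perp_max`` — largest
    excursion orthogonal to the start->target direction.
stability (across M repeated trials)
    endpoint deviation ``s`` — mean distance of trial endpoints from
    their mean endpoint; orbit correlation ``r_orbit`` — mean pairwise
    Pearson correlation of the parallel-displacement time series.
smoothness
    jerk cost ``jc`` = (1/2) integral of the squared third derivative of
    the parallel displacement (lower is smoother; 360 A^2/T^5 for a
    minimum-jerk movement of amplitude A); normalized mean velocity
    ``v_norm`` = mean over peak parallel velocity (1 for constant speed,
    8/15 for minimum jerk; higher is smoother).

All indices are invariant under rigid rotation/translation of the
coordinate frame applied jointly to trajectory, start and target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from itertools import combinations

import numpy as np
from scipy import signal as _signal

#: 7-point central third-derivative stencil, offsets -3..+3, x 1/h^3
_D3_STENCIL = np.array([-1.0, 8.0, -13.0, 0.0, 13.0, -8.0, 1.0]) / 8.0


@dataclass
class TrialTrajectory:
    """One pointing trial: angle series (deg), start and target (deg)."""

    t: np.ndarray
    P: np.ndarray
    start: np.ndarray
    target: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        self.start = np.asarray(self.start, dtype=float)
        self.target = np.asarray(self.target, dtype=float)
        if self.P.shape != (len(self.t), 2):
            raise ValueError("P must be (n, 2) matching t")
        if np.allclose(self.start, self.target):
            raise ValueError("start and target coincide")

    @property
    def fs(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])


@dataclass
class DecomposedTrajectory:
    """Displacement split into parallel/perpendicular components (deg).

    Parallel is the projection onto the unit start->target vector;
    perpendicular is the signed component along that vector rotated +90
    degrees (right-hand convention).
    """

    t: np.ndarray
    p_par: np.ndarray
    p_perp: np.ndarray

    @property
    def fs(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])


def decompose(trial: TrialTrajectory) -> DecomposedTrajectory:
    """Project the trajectory onto the movement direction and its normal."""
    d = trial.target - trial.start
    norm = np.linalg.norm(d)
    if norm == 0.0:
        raise ValueError("zero-length movement direction")
    u = d / norm
    perp = np.array([-u[1], u[0]])
    rel = trial.P - trial.start
    return DecomposedTrajectory(t=trial.t, p_par=rel @ u, p_perp=rel @ perp)


def endpoint_error(trial: TrialTrajectory) -> float:
    """e = || target - P(T) ||."""
    return float(np.linalg.norm(trial.target - trial.P[-1]))


def max_lateral_deviation(decomp: DecomposedTrajectory) -> float:
    """e_perp_max = max_t | P_perp(t) |."""
    return float(np.max(np.abs(decomp.p_perp)))


def endpoint_sd(trials: list[TrialTrajectory]) -> float:
    """Mean distance of trial endpoints from the mean endpoint.

    Endpoints are expressed in the shared parallel/perpendicular frame
    (any orthonormal frame gives the same distances). Requires M >= 2.
    """
    if len(trials) < 2:
        raise ValueError("endpoint deviation needs at least two trials")
    ends = np.array(
        [[decompose(tr).p_par[-1], decompose(tr).p_perp[-1]] for tr in trials]
    )
    mean_end = ends.mean(axis=0)
    return float(np.mean(np.linalg.norm(ends - mean_end, axis=1)))


def _resample_common(series: list[np.ndarray]) -> list[np.ndarray]:
    """Linearly resample all series onto the longest one's length."""
    n = max(len(s) for s in series)
    grid = np.linspace(0.0, 1.0, n)
    out = []
    for s in series:
        src = np.linspace(0.0, 1.0, len(s))
        out.append(np.interp(grid, src, s))
    return out


def orbit_correlation(trials: list[TrialTrajectory]) -> float:
    """Mean pairwise Pearson correlation of parallel-displacement series.

    Trials of unequal length are linearly time-normalized to the longest
    trial before correlating. Zero-variance series make a pair undefined;
    such pairs are excluded with a warning. The double sum over ordered
    pairs equals the unordered-pair mean because Pearson r is symmetric.
    """
    if len(trials) < 2:
        raise ValueError("orbit correlation needs at least two trials")
    series = _resample_common([decompose(tr).p_par for tr in trials])
    rs = []
    skipped = 0
    for i, j in combinations(range(len(series)), 2):
        si, sj = series[i], series[j]
        if np.std(si) == 0.0 or np.std(sj) == 0.0:
            skipped += 1
            continue
        rs.append(float(np.corrcoef(si, sj)[0, 1]))
    if skipped:
        warnings.warn(f"{skipped} trial pair(s) excluded: zero-variance series")
    if not rs:
        raise ValueError("all trial pairs had zero-variance series")
    return float(np.mean(rs))


def _third_derivative(y: np.ndarray, fs: float) -> np.ndarray:
    """7-point central third derivative with odd (antisymmetric) reflection.

    Odd reflection about the edge values preserves odd derivatives at
    the boundary, so the endpoint jerk of smooth point-to-point
    movements (maximal there for a minimum-jerk profile) is estimated
    without the systematic zeroing plain reflection would cause.
    """
    if len(y) < 7:
        raise ValueError("need at least seven samples for the jerk stencil")
    padded = np.pad(y, 3, mode="reflect", reflect_type="odd")
    d3 = np.convolve(padded, _D3_STENCIL[::-1], mode="valid")
    return d3 * fs**3


def jerk_cost(
    decomp: DecomposedTrajectory,
    fs: float | None = None,
    presmooth_hz: float | None = None,
) -> float:
    """jc = (1/2) * integral of (d^3 P_par / dt^3)^2 dt.

    Third derivative via central finite differences, trapezoidal
    quadrature over the supplied window. ``presmooth_hz`` optionally
    low-passes the parallel displacement first (for noisy measured
    data); leave ``None`` for analytic trajectories.
    """
    fs = fs or decomp.fs
    y = decomp.p_par
    if presmooth_hz is not None:
        b, a = _signal.butter(2, presmooth_hz, btype="lowpass", fs=fs)
        y = _signal.filtfilt(b, a, y)
    d3 = _third_derivative(y, fs)
    return float(0.5 * np.trapezoid(d3**2, dx=1.0 / fs))


def normalized_mean_velocity(
    decomp: DecomposedTrajectory, fs: float | None = None
) -> float:
    """v_norm = mean(v_par) / max(v_par) over the supplied window."""
    fs = fs or decomp.fs
    v = np.gradient(decomp.p_par, 1.0 / fs)
    peak = np.max(v)
    if peak <= 0.0:
        raise ValueError("non-positive peak parallel velocity")
    return float(np.mean(v) / peak)


def reaching_time(
    trial: TrialTrajectory,
    onset_frac: float = 0.05,
    arrival_radius: float = 2.0,
    dwell_ms: float = 100.0,
) -> tuple[float, int, int]:
    """Movement duration from onset to arrival.

    Onset: first sample where the parallel velocity exceeds
    ``onset_frac`` of its peak. Arrival: first sample after onset where
    the position enters a ball of ``arrival_radius`` degrees around the
    movement endpoint and stays inside for at least ``dwell_ms`` (and
    through the end of the recording). Returns (duration_s, onset_index,
    arrival_index).
    """
    decomp = decompose(trial)
    dt = 1.0 / trial.fs
    v = np.gradient(decomp.p_par, dt)
    peak = np.max(np.abs(v))
    if peak <= 0.0:
        raise ValueError("no movement detected: zero peak velocity")
    above = np.abs(v) > onset_frac * peak
    if not np.any(above):
        raise ValueError("movement onset never detected")
    onset = int(np.argmax(above))
    dist = np.linalg.norm(trial.P - trial.P[-1], axis=1)
    inside = dist <= arrival_radius
    dwell = max(1, int(round(dwell_ms * 1e-3 * trial.fs)))
    arrival = None
    # last exit from the ball defines the final entry; require the dwell
    outside_idx = np.flatnonzero(~inside[onset:]) + onset
    entry = onset if len(outside_idx) == 0 else int(outside_idx[-1]) + 1
    if entry < len(inside) and np.all(inside[entry:]) and (
        len(inside) - entry >= dwell
    ):
        arrival = entry
    if arrival is None:
        raise ValueError("arrival (enter and stay within radius) never detected")
    return float(trial.t[arrival] - trial.t[onset]), onset, arrival


@dataclass
class MetricReport:
    """Per-trial (means) and per-set pointing indices with units.

    e, e_perp_max, s in degrees; jc in deg^2 s^-5; r_orbit and v_norm
    dimensionless; reaching_time in seconds.
    """

    e: float
    e_perp_max: float
    s: float
    r_orbit: float
    jc: float
    v_norm: float
    reaching_time: float

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate_trial(
    trial: TrialTrajectory,
    window: bool = True,
    onset_frac: float = 0.05,
    arrival_radius: float = 2.0,
    dwell_ms: float = 100.0,
    presmooth_hz: float | None = None,
) -> dict:
    """All single-trial indices.

    With ``window=True`` the smoothness integrals run over the
    onset-to-arrival movement window (falling back to the full recording
    if onset/arrival detection fails); endpoint and lateral indices
    always use the full trial.
    """
    decomp = decompose(trial)
    out = {
        "e": endpoint_error(trial),
        "e_perp_max": max_lateral_deviation(decomp),
    }
    lo, hi = 0, len(trial.t)
    rt = float("nan")
    try:
        rt, onset, arrival = reaching_time(
            trial, onset_frac=onset_frac, arrival_radius=arrival_radius,
            dwell_ms=dwell_ms,
        )
        if window and arrival + 1 - onset >= 7:
            lo, hi = onset, arrival + 1
    except ValueError:
        pass
    sub = DecomposedTrajectory(
        t=trial.t[lo:hi], p_par=decomp.p_par[lo:hi], p_perp=decomp.p_perp[lo:hi]
    )
    out["jc"] = jerk_cost(sub, fs=trial.fs, presmooth_hz=presmooth_hz)
    out["v_norm"] = normalized_mean_velocity(sub, fs=trial.fs)
    out["reaching_time"] = rt
    return out


def evaluate_trial_set(trials: list[TrialTrajectory], **kwargs) -> MetricReport:
    """Aggregate a set of repeated trials into one report.

    Single-trial indices are averaged over trials; s and r_orbit are
    computed across the set.
    """
    per_trial = [evaluate_trial(tr, **kwargs) for tr in trials]
    mean = {
        key: float(np.nanmean([pt[key] for pt in per_trial]))
        for key in ("e", "e_perp_max", "jc", "v_norm", "reaching_time")
    }
    return MetricReport(
        e=mean["e"],
        e_perp_max=mean["e_perp_max"],
        s=endpoint_sd(trials),
        r_orbit=orbit_correlation(trials),
        jc=mean["jc"],
        v_norm=mean["v_norm"],
        reaching_time=mean["reaching_time"],
    )
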