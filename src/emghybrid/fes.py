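"""Functional-electrical-stimulation model: sigmoid current-to-angle
characteristic, its inverse for open-loop current commands, and
least-squares calibration.

Steady-state wrist angle under stimulation is modelled as the logistic

    theta(I) = d / (1 + exp(b (c - I)))

with b the rise rapidity (1/mA), c the half-maximum current (mA) and d
the maximum attainable angle (deg). The inverse,

    I(theta) = c - (1/b) ln(d / theta - 1),

converts a commanded angle into a stimulation current. Only the
steady-state mapping is modelled — the dynamic response of muscle to
stimulation is not — so control is open loop; during instruction the
robot dominates the realized motion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .config import DIRECTION_VECTORS, FesConfig
from .trajectory import SampledTrajectory

#: commanded angles are clipped into [EPS_THETA*d, (1-EPS_THETA)*d]
#: to keep the logarithm in the inverse finite
EPS_THETA = 1e-3


class FitFailure(RuntimeError):
    """Nonlinear least squares failed or the curve is unidentifiable."""


@dataclass
class FesParams:
    """Sigmoid parameters: b (1/mA), c (mA), d (deg)."""

    b: float
    c: float
    d: float
    residual: float = 0.0

    def __post_init__(self) -> None:
        if self.b <= 0 or self.d <= 0:
            raise ValueError("require b > 0 and d > 0")


def angle_from_current(current, params: FesParams):
    """Steady-state joint angle theta = d / (1 + exp(b (c - I)))."""
    current = np.asarray(current, dtype=float)
    return params.d / (1.0 + np.exp(params.b * (params.c - current)))


def current_from_angle(theta, params: FesParams, clip: bool = True):
    """Invert the sigmoid: I = c - (1/b) ln(d/theta - 1).

    Angles at or beyond the model range (0, d) are clipped into
    [eps*d, (1-eps)*d] with eps = 1e-3 (a warning is emitted); pass
    ``clip=False`` to get a domain error instead.
    """
    theta = np.asarray(theta, dtype=float)
    lo, hi = EPS_THETA * params.d, (1.0 - EPS_THETA) * params.d
    out_of_range = (theta < lo) | (theta > hi)
    if np.any(out_of_range):
        if not clip:
            raise ValueError("angle outside the open interval (0, d)")
        warnings.warn(
            f"{int(np.sum(out_of_range))} commanded angle(s) clipped into "
            f"[{lo:.3g}, {hi:.3g}] deg"
        )
        theta = np.clip(theta, lo, hi)
    return params.c - np.log(params.d / theta - 1.0) / params.b


def _sigmoid(I, b, c, d):
    return d / (1.0 + np.exp(b * (c - I)))


def fit_params(currents, angles) -> FesParams:
    """Calibrate (b, c, d) by nonlinear least squares on (I, theta) pairs.

    Stepwise current increases with the measured steady-state angles are
    the expected input: strictly increasing currents, at least four
    points. Initialization: d0 = 1.05 x max angle, c0 = current at half
    the maximum angle, b0 from the local slope there. Deterministic for
    given data.
    """
    currents = np.asarray(currents, dtype=float)
    angles = np.asarray(angles, dtype=float)
    if currents.ndim != 1 or currents.shape != angles.shape:
        raise ValueError("currents and angles must be matching 1-D arrays")
    if len(currents) < 4:
        raise ValueError("need at least four calibration points")
    if np.any(np.diff(currents) <= 0):
        raise ValueError("calibration currents must be strictly increasing")
    span = angles.max() - angles.min()
    if span < 1e-9 * max(1.0, abs(angles.max())):
        raise FitFailure("flat calibration curve: maximum angle d unidentifiable")

    d0 = 1.05 * angles.max()
    half = 0.5 * angles.max()
    c0 = float(np.interp(half, angles, currents)) if np.all(np.diff(angles) >= 0) \
        else float(currents[np.argmin(np.abs(angles - half))])
    # logistic slope at c is b*d/4; estimate the slope numerically near c0
    slope = float(np.gradient(angles, currents)[np.argmin(np.abs(currents - c0))])
    b0 = max(4.0 * abs(slope) / d0, 1e-3)
    try:
        popt, _ = curve_fit(
            _sigmoid, currents, angles, p0=[b0, c0, d0],
            bounds=([1e-9, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - rare with sane data
        raise FitFailure(f"sigmoid fit did not converge: {exc}") from exc
    residual = float(np.linalg.norm(angles - _sigmoid(currents, *popt)))
    return FesParams(b=float(popt[0]), c=float(popt[1]), d=float(popt[2]),
                     residual=residual)


def stimulation_series(
    traj: SampledTrajectory,
    params_by_muscle: dict,
    direction_to_muscle: dict,
    fes_cfg: FesConfig | None = None,
) -> pd.DataFrame:
    """Open-loop stimulation commands realizing a commanded trajectory.

    Per sample, the active direction is the dominant axis of the
    displacement from the trajectory start (flexion = +X, radial = +Y,
    extension = -X, ulnar = -Y); the mapped muscle is stimulated with the
    current whose steady-state angle equals the displacement magnitude
    along that axis. No feedback on the realized angle is used.

    Returns a DataFrame with columns ``time, muscle, current_mA,
    angle_cmd_deg, clipped`` plus the fixed pulse parameters.
    """
    fes_cfg = fes_cfg or FesConfig()
    disp = traj.P - traj.P[0]
    rows = []
    for i, t in enumerate(traj.t):
        axis = int(np.argmax(np.abs(disp[i])))
        sign = 1.0 if disp[i, axis] >= 0 else -1.0
        direction = next(
            name for name, vec in DIRECTION_VECTORS.items()
            if vec[axis] == sign and vec[1 - axis] == 0.0
        )
        if direction not in direction_to_muscle:
            raise KeyError(f"no muscle mapped for direction {direction!r}")
        muscle = direction_to_muscle[direction]
        params = params_by_muscle[muscle]
        angle = abs(disp[i, axis])
        clipped = angle < EPS_THETA * params.d or angle > (1 - EPS_THETA) * params.d
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            current = float(current_from_angle(angle, params))
        rows.append((float(t), muscle, current, angle, clipped))
    df = pd.DataFrame(
        rows, columns=["time", "muscle", "current_mA", "angle_cmd_deg", "clipped"]
    )
    df["pulse_frequency_hz"] = fes_cfg.pulse_frequency
    df["pulse_width_ms"] = fes_cfg.pulse_width_ms
    return df
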