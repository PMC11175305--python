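"""Synthetic study data with known ground truth.

Three generators make the whole pipeline testable without recordings:

* :func:`generate_emg` — four-channel surface EMG emulating the wrist
  montage (flexor carpi ulnaris/radialis, extensor carpi
  ulnaris/radialis). Each channel is band-limited Gaussian noise
  (20-450 Hz interference-pattern surrogate) amplitude-modulated so
  that its rectified-smoothed envelope tracks
  rest + peak * pattern_l * shape(t), where the per-class coordination
  ``pattern`` sums to one across channels. Slow multiplicative noise on
  the envelope models contraction variability.
* :func:`generate_trial` — noisy 2-DOF pointing trajectories: a
  minimum-jerk backbone toward the target plus endpoint bias, isotropic
  endpoint noise, a half-sine lateral bow, and sinusoidal tremor.
  Session-to-session motor learning is modelled as multiplicative decay
  of each skill parameter toward a floor.
* :func:`generate_fes_calibration` — stepwise-current calibration
  sweeps from the sigmoid current-angle model plus Gaussian noise.

Every generator takes an explicit seed or Generator; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _signal

from .config import DIRECTIONS
from .fes import FesParams, angle_from_current
from .metrics import TrialTrajectory
from .preprocess import RawEMGRecord
from .trajectory import TrajectorySpec, minimum_jerk

#: idealized muscle-coordination patterns for the four wrist movements,
#: channel order (FCU, FCR, ECU, ECR); rows sum to one
DEFAULT_PATTERNS = {
    "flexion": np.array([0.45, 0.45, 0.05, 0.05]),
    "radial": np.array([0.05, 0.45, 0.05, 0.45]),
    "extension": np.array([0.05, 0.05, 0.45, 0.45]),
    "ulnar": np.array([0.45, 0.05, 0.45, 0.05]),
}


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass
class EMGGenSpec:
    """Parameters of the synthetic EMG session.

    ``patterns`` maps class label -> L-vector coordination profile
    (sum 1). The activation envelope ramps up over ``ramp_s`` after
    ``lead_s`` of rest, holds a plateau at ``peak`` (arbitrary amplitude
    units), and ramps down before ``tail_s`` of rest. ``noise_sd`` is
    the s.d. of slow multiplicative envelope noise (fraction of the
    local envelope). The carrier is Gaussian noise bandpassed to
    ``carrier_band`` Hz.
    """

    patterns: dict = field(default_factory=lambda: {
        k: v.copy() for k, v in DEFAULT_PATTERNS.items()
    })
    peak: float = 1.0
    rest_level: np.ndarray | float = 0.02
    noise_sd: float = 0.1
    carrier_band: tuple = (20.0, 450.0)
    duration: float = 1.6
    lead_s: float = 0.5
    ramp_s: float = 0.1
    tail_s: float = 0.1
    fs: float = 1000.0

    def __post_init__(self) -> None:
        for name, p in self.patterns.items():
            p = np.asarray(p, dtype=float)
            if abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
                raise ValueError(f"pattern {name!r} must be nonnegative, sum 1")
            self.patterns[name] = p
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    @property
    def n_channels(self) -> int:
        return len(next(iter(self.patterns.values())))


def _activation_shape(spec: EMGGenSpec) -> np.ndarray:
    """Raised-cosine ramp / plateau / ramp-down profile in [0, 1]."""
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs
    up0, up1 = spec.lead_s, spec.lead_s + spec.ramp_s
    dn1 = spec.duration - spec.tail_s
    dn0 = dn1 - spec.ramp_s
    shape = np.zeros(n)
    rising = (t >= up0) & (t < up1)
    shape[rising] = 0.5 * (1 - np.cos(np.pi * (t[rising] - up0) / spec.ramp_s))
    shape[(t >= up1) & (t < dn0)] = 1.0
    falling = (t >= dn0) & (t < dn1)
    shape[falling] = 0.5 * (1 + np.cos(np.pi * (t[falling] - dn0) / spec.ramp_s))
    return shape


def _carrier(spec: EMGGenSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-envelope band-limited noise carriers, shape (n, L).

    Scaled so that the mean rectified value is ~1, making the smoothed
    rectified envelope track the modulating amplitude.
    """
    white = rng.standard_normal((n, spec.n_channels))
    lo, hi = spec.carrier_band
    b, a = _signal.butter(2, [lo, min(hi, 0.49 * spec.fs)], btype="bandpass",
                          fs=spec.fs)
    band = _signal.lfilter(b, a, white, axis=0)
    band /= band.std(axis=0, keepdims=True)
    return band / np.sqrt(2.0 / np.pi)  # E|N(0,1)| = sqrt(2/pi)


def generate_emg(
    spec: EMGGenSpec, class_label: str, seed=0
) -> tuple[RawEMGRecord, dict]:
    """One synthetic recording of the given movement class.

    Returns the raw record plus ground truth: the target envelope, a
    per-sample ``active`` mask (plateau region), and the class label.
    """
    rng = _rng(seed)
    pattern = spec.patterns[class_label]
    shape = _activation_shape(spec)
    n = len(shape)
    t = np.arange(n) / spec.fs
    rest = np.broadcast_to(
        np.asarray(spec.rest_level, dtype=float), (spec.n_channels,)
    )
    env = rest[None, :] + spec.peak * shape[:, None] * pattern[None, :]
    if spec.noise_sd > 0:
        slow = rng.standard_normal((n, spec.n_channels))
        b, a = _signal.butter(2, 5.0, btype="lowpass", fs=spec.fs)
        slow = _signal.lfilter(b, a, slow, axis=0)
        slow /= max(slow.std(), 1e-12)
        env = env * np.clip(1.0 + spec.noise_sd * slow, 0.05, None)
    signals = env * _carrier(spec, n, rng)
    truth = {
        "class": class_label,
        "envelope": env,
        "active": shape >= 1.0,
    }
    return RawEMGRecord(t=t, signals=signals), truth


def subject_patterns(rng, jitter: float = 0.08) -> dict:
    """Per-subject coordination patterns: jittered, renormalized prototypes."""
    rng = _rng(rng)
    out = {}
    for name, proto in DEFAULT_PATTERNS.items():
        p = np.clip(proto + jitter * rng.standard_normal(proto.shape), 0.01, None)
        out[name] = p / p.sum()
    return out


def generate_session(
    spec: EMGGenSpec, seed=0, classes: tuple = DIRECTIONS
) -> dict:
    """A full calibration + training session for one subject.

    Returns rest and per-class voluntary/training records (training
    reuses the voluntary recordings, as in the emulated protocol where each
    movement is performed once) and an independent held-out recording
    per class.
    """
    rng = _rng(seed)
    rest_spec = replace(spec, peak=0.0)
    rest_rec, _ = generate_emg(rest_spec, classes[0], rng)
    session = {"rest": rest_rec, "voluntary": {}, "heldout": {}}
    for name in classes:
        session["voluntary"][name] = generate_emg(spec, name, rng)
        session["heldout"][name] = generate_emg(spec, name, rng)
    return session


@dataclass
class SubjectSkill:
    """Error structure of a simulated subject's pointing.

    All amplitudes in degrees, durations in seconds. ``decay`` is the
    per-session multiplicative factor applied to each error parameter
    (endpoint bias, endpoint noise, curvature, tremor) toward
    ``floor_frac`` of its initial value; ``duration_decay`` pulls the
    movement duration toward ``duration_target``. Decay factors in
    (0, 1]; 1 means no learning.
    """

    endpoint_bias: np.ndarray = field(default_factory=lambda: np.array([2.0, 0.0]))
    endpoint_noise_sd: float = 2.0
    curvature: float = 4.0
    tremor_amp: float = 0.5
    tremor_freq: float = 8.0
    duration: float = 2.5
    decay: float = 1.0
    floor_frac: float = 0.1
    duration_decay: float = 1.0
    duration_target: float = 2.0

    def __post_init__(self) -> None:
        self.endpoint_bias = np.asarray(self.endpoint_bias, dtype=float)
        for name in ("endpoint_noise_sd", "curvature", "tremor_amp", "tremor_freq"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("decay", "duration_decay"):
            if not (0.0 < getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1]")


def skill_at_session(skill: SubjectSkill, session: int) -> SubjectSkill:
    """Skill parameters after ``session`` training sessions.

    Each error parameter p follows p_s = floor + (p_0 - floor) * decay^s
    with floor = floor_frac * p_0; the duration relaxes toward
    ``duration_target`` at rate ``duration_decay``.
    """
    f = skill.decay**session

    def relax(v0):
        floor = skill.floor_frac * v0
        return floor + (v0 - floor) * f

    fd = skill.duration_decay**session
    return replace(
        skill,
        endpoint_bias=relax(skill.endpoint_bias),
        endpoint_noise_sd=relax(skill.endpoint_noise_sd),
        curvature=relax(skill.curvature),
        tremor_amp=relax(skill.tremor_amp),
        duration=skill.duration_target + (skill.duration - skill.duration_target) * fd,
    )


def generate_trial(
    skill: SubjectSkill,
    start: np.ndarray,
    target: np.ndarray,
    fs: float = 1000.0,
    rng=0,
) -> TrialTrajectory:
    """One noisy pointing trial toward ``target``.

    Minimum-jerk backbone to target + bias + isotropic endpoint noise,
    plus a half-sine lateral bow of amplitude ``curvature`` and additive
    sinusoidal tremor on both components.
    """
    rng = _rng(rng)
    start = np.asarray(start, dtype=float)
    target = np.asarray(target, dtype=float)
    endpoint = (
        target + skill.endpoint_bias
        + skill.endpoint_noise_sd * rng.standard_normal(2)
    )
    spec = TrajectorySpec(start=start, target=endpoint, duration=skill.duration)
    base = minimum_jerk(spec, fs_out=fs)
    t = base.t
    tau = t / skill.duration
    d = endpoint - start
    u = d / np.linalg.norm(d)
    perp = np.array([-u[1], u[0]])
    bow_sign = rng.choice([-1.0, 1.0])
    P = base.P + (bow_sign * skill.curvature * np.sin(np.pi * tau))[:, None] * perp
    if skill.tremor_amp > 0:
        phases = rng.uniform(0.0, 2.0 * np.pi, size=2)
        tremor = skill.tremor_amp * np.sin(
            2.0 * np.pi * skill.tremor_freq * t[:, None] + phases[None, :]
        )
        # fade tremor in/out so the endpoints stay exact
        fade = np.sin(np.pi * tau)[:, None]
        P = P + tremor * fade
    return TrialTrajectory(t=t, P=P, start=start, target=target)


def generate_fes_calibration(
    true_params: FesParams,
    i_max: float = 20.0,
    step: float = 1.0,
    noise_sd: float = 0.0,
    seed=0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stepwise-current calibration sweep (I, theta) from the sigmoid model."""
    rng = _rng(seed)
    currents = np.arange(0.0, i_max + 0.5 * step, step)
    angles = angle_from_current(currents, true_params)
    if noise_sd > 0:
        angles = angles + noise_sd * rng.standard_normal(angles.shape)
    return currents, angles
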