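"""Surface-EMG preprocessing: filtering, envelope extraction, normalization,
muscle-coordination features and the activation gate.

The chain is the standard one for amplitude-based myoelectric control:
a causal second-order Butterworth bandpass isolates the physiological
band, full-wave rectification plus a second-order low-pass extracts the
amplitude envelope E_l(t), per-channel calibration against rest and
voluntary-maximum recordings yields a normalized envelope

    E'_l(t) = (E_l(t) - E_l^st) / (E_l^max - E_l^st),   clipped below at 0,

and the coordination feature vector divides out overall effort,

    x_l(t) = E'_l(t) / sum_l E'_l(t),

so that x(t) encodes *which* muscles co-contract independently of how
hard. The mean normalized envelope F(t) = (1/L) sum_l E'_l(t) gates
whether the system acts at all.

All filtering is causal (single-pass ``lfilter``), matching on-line
operation; a second-order low-pass at ``fc_smooth`` Hz has group delay
of roughly 1/(2*pi*fc_smooth) seconds near DC, and envelope statistics
computed before the filter settles are unreliable, so calibration
excludes an initial settle-in window of three smoothing time constants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .config import SignalConfig

#: below this summed normalized envelope the coordination vector is
#: undefined; a uniform vector is substituted and the sample flagged
SUBTHRESHOLD_EPS = 1e-6


class CalibrationError(ValueError):
    """Voluntary-maximum envelope does not exceed the rest baseline."""


@dataclass
class RawEMGRecord:
    """Uniformly sampled multichannel EMG, ``signals`` of shape (n, L)."""

    t: np.ndarray
    signals: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if self.signals.shape[0] != self.t.shape[0]:
            raise ValueError("time axis and signals disagree in length")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[1]


@dataclass
class EnvelopeRecord:
    """Smoothed rectified EMG amplitude with optional calibration baselines.

    ``rest_baseline`` holds the per-channel rest level E_l^st and
    ``max_level`` the per-channel voluntary maximum E_l^max; both are
    ``None`` until :func:`calibrate` fills them in.
    """

    t: np.ndarray
    envelope: np.ndarray
    rest_baseline: np.ndarray | None = None
    max_level: np.ndarray | None = None

    @property
    def n_channels(self) -> int:
        return self.envelope.shape[1]


@dataclass
class FeatureSequence:
    """Time series of coordination vectors x(t) with activation F(t).

    ``x`` has shape (n, L); each row sums to one. ``subthreshold`` marks
    rows where the summed envelope was too small for the ratio to be
    meaningful (a uniform vector is substituted there). ``gate`` is the
    debounced drive signal derived from F(t).
    """

    t: np.ndarray
    x: np.ndarray
    activation: np.ndarray
    gate: np.ndarray
    subthreshold: np.ndarray


def concat_envelopes(records: list[EnvelopeRecord]) -> EnvelopeRecord:
    """Stitch envelope records end to end (e.g. the per-movement voluntary
    recordings, so calibration takes each channel's maximum over all
    desired motions)."""
    env = np.concatenate([r.envelope for r in records], axis=0)
    dt = records[0].t[1] - records[0].t[0]
    return EnvelopeRecord(t=np.arange(env.shape[0]) * dt, envelope=env)


def settle_samples(cfg: SignalConfig, n_time_constants: float = 3.0) -> int:
    """Samples to discard while the smoothing low-pass settles.

    Uses the first-order-equivalent time constant 1/(2*pi*fc_smooth).
    """
    tau = 1.0 / (2.0 * np.pi * cfg.fc_smooth)
    return int(round(n_time_constants * tau * cfg.fs))


def _butter_bandpass(cfg: SignalConfig):
    return signal.butter(
        2, [cfg.fc_low, cfg.fc_high], btype="bandpass", fs=cfg.fs
    )


def _butter_lowpass(cfg: SignalConfig):
    return signal.butter(2, cfg.fc_smooth, btype="lowpass", fs=cfg.fs)


def bandpass(raw: RawEMGRecord, cfg: SignalConfig) -> RawEMGRecord:
    """Causal second-order Butterworth bandpass, channel by channel."""
    if cfg.fc_high >= cfg.fs / 2.0:
        raise ValueError("fc_high must be below the Nyquist frequency")
    b, a = _butter_bandpass(cfg)
    filtered = signal.lfilter(b, a, raw.signals, axis=0)
    return RawEMGRecord(t=raw.t, signals=filtered)


def rectify_smooth(filtered: RawEMGRecord, cfg: SignalConfig) -> EnvelopeRecord:
    """Full-wave rectification followed by a causal second-order low-pass."""
    b, a = _butter_lowpass(cfg)
    env = signal.lfilter(b, a, np.abs(filtered.signals), axis=0)
    return EnvelopeRecord(t=filtered.t, envelope=env)


def calibrate(
    rest: EnvelopeRecord,
    voluntary_max: EnvelopeRecord,
    cfg: SignalConfig,
) -> EnvelopeRecord:
    """Derive per-channel baselines from rest and voluntary recordings.

    E_l^st is the mean rest envelope after the settle-in window; E_l^max
    is the maximum envelope during the voluntary recording. Returns a
    copy of ``voluntary_max`` carrying the baselines (attach them to any
    other record with :func:`dataclasses.replace`).
    """
    skip = settle_samples(cfg)
    if rest.envelope.shape[0] <= skip or voluntary_max.envelope.shape[0] <= skip:
        raise ValueError("calibration recordings shorter than the settle-in window")
    rest_baseline = rest.envelope[skip:].mean(axis=0)
    max_level = voluntary_max.envelope[skip:].max(axis=0)
    span = max_level - rest_baseline
    bad = span <= 1e-9 * np.maximum(np.abs(max_level), 1e-12)
    if np.any(bad):
        raise CalibrationError(
            "voluntary maximum does not exceed rest baseline on channel(s) "
            f"{np.flatnonzero(bad).tolist()}"
        )
    return replace(voluntary_max, rest_baseline=rest_baseline, max_level=max_level)


def normalize(env: EnvelopeRecord) -> np.ndarray:
    """Normalized envelope E' = (E - E^st)/(E^max - E^st), clipped at 0."""
    if env.rest_baseline is None or env.max_level is None:
        raise ValueError("EnvelopeRecord has no calibration baselines; run calibrate")
    span = env.max_level - env.rest_baseline
    eprime = (env.envelope - env.rest_baseline) / span
    return np.clip(eprime, 0.0, None)


def feature_vector(eprime: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sum-to-one coordination vectors from normalized envelopes.

    Accepts a single L-vector or an (n, L) array. Rows whose sum falls
    below :data:`SUBTHRESHOLD_EPS` get the uniform vector 1/L and are
    flagged in the returned boolean mask (the gate excludes them anyway).
    """
    arr = np.atleast_2d(np.asarray(eprime, dtype=float))
    total = arr.sum(axis=1)
    sub = total < SUBTHRESHOLD_EPS
    safe_total = np.where(sub, 1.0, total)
    x = arr / safe_total[:, None]
    x[sub] = 1.0 / arr.shape[1]
    if np.ndim(eprime) == 1:
        return x[0], sub[0]
    return x, sub


def activation_level(eprime: np.ndarray) -> np.ndarray:
    """Muscle activation level F = mean over channels of E'."""
    arr = np.asarray(eprime, dtype=float)
    return arr.mean(axis=-1)


def gate(
    activation: np.ndarray, threshold: float, debounce_samples: int
) -> np.ndarray:
    """Debounced drive signal.

    True at sample t iff F >= threshold for ``debounce_samples``
    consecutive samples ending at t.
    """
    if threshold <= 0:
        raise ValueError("gate threshold must be positive")
    above = np.asarray(activation) >= threshold
    out = np.zeros_like(above, dtype=bool)
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        out[i] = run >= debounce_samples
    return out


def extract_features(
    raw: RawEMGRecord,
    cfg: SignalConfig,
    rest_baseline: np.ndarray,
    max_level: np.ndarray,
) -> FeatureSequence:
    """Full chain raw EMG -> gated coordination features."""
    env = rectify_smooth(bandpass(raw, cfg), cfg)
    env = replace(env, rest_baseline=np.asarray(rest_baseline),
                  max_level=np.asarray(max_level))
    eprime = normalize(env)
    x, sub = feature_vector(eprime)
    f = activation_level(eprime)
    g = gate(f, cfg.gate_threshold, cfg.debounce_samples)
    if np.any(g & sub):
        warnings.warn("gate open on sub-threshold samples; check calibration")
    return FeatureSequence(t=raw.t, x=x, activation=f, gate=g, subthreshold=sub)
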