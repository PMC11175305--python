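"""Configuration objects and defaults for the hybrid-rehabilitation simulator.

Defaults describe the reference 2-DOF wrist-pointing protocol:
four-channel surface EMG sampled at 1 kHz, a four-class recurrent
probabilistic classifier, 20-degree pointing targets and a 2 s
instruction / 3 s training / 1 s feedback schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
import numpy as np
import yaml

#: canonical direction labels for the 2-DOF wrist pointing task,
#: in class-index order. X = flexion-extension (flexion positive),
#: Y = radial-ulnar deviation (radial positive).
DIRECTIONS = ("flexion", "radial", "extension", "ulnar")

#: unit vectors of the four pointing directions in (X, Y) joint space
DIRECTION_VECTORS = {
    "flexion": np.array([1.0, 0.0]),
    "radial": np.array([0.0, 1.0]),
    "extension": np.array([-1.0, 0.0]),
    "ulnar": np.array([0.0, -1.0]),
}

#: servo range of motion per axis (degrees); trajectories beyond this
#: are rejected rather than silently clipped
JOINT_RANGE_DEG = 45.0


@dataclass
class SignalConfig:
    """EMG acquisition and preprocessing parameters.

    Parameters
    ----------
    fs : float
        Sampling frequency in Hz.
    fc_low, fc_high : float
        Bandpass corner frequencies in Hz of the second-order
        Butterworth front-end filter.
    fc_smooth : float
        Cutoff in Hz of the second-order low-pass used to smooth the
        full-wave rectified signal into an amplitude envelope.
    n_channels : int
        Number of electrode channels L.
    gate_threshold : float
        Muscle-activation level F(t) above which the system drives.
    debounce_ms : float
        F(t) must stay above threshold this long before the gate opens.
    """

    fs: float = 1000.0
    fc_low: float = 1.0
    fc_high: float = 250.0
    fc_smooth: float = 1.0
    n_channels: int = 4
    gate_threshold: float = 0.2
    debounce_ms: float = 50.0

    def __post_init__(self) -> None:
        if self.fs <= 2.0 * self.fc_high:
            raise ValueError(
                f"fs={self.fs} must exceed twice fc_high={self.fc_high} (Nyquist)"
            )
        if not (0.0 < self.fc_low < self.fc_high):
            raise ValueError("require 0 < fc_low < fc_high")
        if self.fc_smooth <= 0.0:
            raise ValueError("fc_smooth must be positive")
        if self.n_channels < 2:
            raise ValueError("need at least two EMG channels")

    @property
    def debounce_samples(self) -> int:
        return max(1, int(round(self.debounce_ms * 1e-3 * self.fs)))


@dataclass
class NetworkConfig:
    """Architecture of the recurrent log-linearized Gaussian-mixture network.

    ``n_classes`` (C) motion classes, ``n_states`` (K) hidden Markov states
    per class, ``n_components`` (M) Gaussian components per state, and
    decisions taken over windows of ``seq_len`` feature samples.
    """

    n_classes: int = 4
    n_states: int = 2
    n_components: int = 2
    seq_len: int = 50
    input_dim: int = 4

    def __post_init__(self) -> None:
        for name in ("n_classes", "n_states", "n_components", "seq_len", "input_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def expanded_dim(self) -> int:
        """Dimension H = 1 + L(L+3)/2 of the nonlinearly expanded input."""
        L = self.input_dim
        return 1 + L * (L + 3) // 2


@dataclass
class ModeSchedule:
    """Timing of the instruction / training / feedback control modes."""

    t_instruct: float = 2.0
    t_train: float = 3.0
    t_feedback: float = 1.0
    target_map: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.t_instruct, self.t_train, self.t_feedback) <= 0:
            raise ValueError("all schedule durations must be positive")


def default_target_map(amplitude_deg: float = 20.0) -> dict:
    """Per-direction pointing targets at the given amplitude (degrees)."""
    return {
        name: amplitude_deg * vec for name, vec in DIRECTION_VECTORS.items()
    }


@dataclass
class FesConfig:
    """Fixed stimulation pulse parameters (frequency Hz, width ms)."""

    pulse_frequency: float = 50.0
    pulse_width_ms: float = 0.2


@dataclass
class ExperimentConfig:
    """Layout of the simulated motor-learning experiment.

    Each group is pre-evaluated ``n_pre`` times without feedback, trains
    for ``n_sessions`` sessions alternating with sequential evaluations,
    is post-evaluated ``n_post`` times, and optionally re-evaluated for
    retention. Pointing is performed in all four directions per trial.
    """

    groups: tuple = ("hybrid", "visual_feedback")
    n_subjects_per_group: int = 6
    n_pre: int = 3
    n_sessions: int = 20
    n_post: int = 3
    n_retention: int = 3
    retention: bool = True
    target_amplitude_deg: float = 20.0
    schedule: ModeSchedule = field(default_factory=ModeSchedule)
    signal: SignalConfig = field(default_factory=SignalConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    fes: FesConfig = field(default_factory=FesConfig)
    fs_traj: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects_per_group, self.n_pre, self.n_sessions, self.n_post) < 1:
            raise ValueError("subject and evaluation counts must be >= 1")
        if self.target_amplitude_deg <= 0 or self.target_amplitude_deg > JOINT_RANGE_DEG:
            raise ValueError(
                f"target amplitude must lie in (0, {JOINT_RANGE_DEG}] degrees"
            )
        if not self.schedule.target_map:
            self.schedule.target_map = default_target_map(self.target_amplitude_deg)


def load_config(path: str | Path) -> ExperimentConfig:
    """Load an :class:`ExperimentConfig` from a YAML file.

    Unknown keys raise; nested sections (``schedule``, ``signal``,
    ``network``, ``fes``) map onto their dataclasses.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    nested = {
        "schedule": ModeSchedule,
        "signal": SignalConfig,
        "network": NetworkConfig,
        "fes": FesConfig,
    }
    for key, value in raw.items():
        if key in nested:
            kwargs[key] = nested[key](**value)
        else:
            kwargs[key] = value
    if "groups" in kwargs:
        kwargs["groups"] = tuple(kwargs["groups"])
    return ExperimentConfig(**kwargs)


def dump_config(cfg: ExperimentConfig, path: str | Path) -> None:
    """Write a config back out as YAML (targets serialized as lists)."""
    data = asdict(cfg)
    data["schedule"]["target_map"] = {
        k: [float(x) for x in v] for k, v in cfg.schedule.target_map.items()
    }
    data["groups"] = list(cfg.groups)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
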