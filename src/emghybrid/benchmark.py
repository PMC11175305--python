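"""End-to-end classifier benchmark on synthetic multi-subject EMG.

Reproduces the reference training protocol in silico: per subject, one
recording per movement is made, 0.5 s (500 samples at 1 kHz) of the
contraction is kept as training data, the recurrent network is trained
on sliding decision windows, and held-out recordings of the same
movements are classified window by window. The headline number is the
mean held-out accuracy across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classifier import predict_batch, train, windows_from_features
from .config import DIRECTIONS, NetworkConfig, SignalConfig
from .preprocess import (bandpass, calibrate, concat_envelopes,
                         extract_features, rectify_smooth)
from .synth import EMGGenSpec, generate_session, subject_patterns

#: samples of each voluntary recording kept for training (0.5 s at 1 kHz)
TRAIN_SAMPLES = 500


@dataclass
class SubjectResult:
    """Per-subject benchmark outcome."""

    accuracy: float
    confusion: np.ndarray
    train_accuracy: float
    n_heldout: int


def run_subject(
    subject_seed: int,
    signal_cfg: SignalConfig | None = None,
    network_cfg: NetworkConfig | None = None,
    noise_sd: float = 0.1,
    window_stride: int = 5,
    n_heldout_windows: int = 100,
    max_iter: int = 300,
) -> SubjectResult:
    """Train and evaluate the classifier for one simulated subject.

    The subject gets individually jittered coordination patterns; rest
    and per-movement voluntary recordings calibrate the envelopes; the
    last 0.5 s of each voluntary contraction trains the network on
    length-``seq_len`` windows (stride ``window_stride``); gated windows
    from independent held-out recordings are classified.
    """
    signal_cfg = signal_cfg or SignalConfig()
    network_cfg = network_cfg or NetworkConfig()
    rng = np.random.default_rng(subject_seed)
    spec = EMGGenSpec(
        patterns=subject_patterns(rng),
        noise_sd=noise_sd,
        fs=signal_cfg.fs,
    )
    session = generate_session(spec, seed=rng)

    rest_env = rectify_smooth(bandpass(session["rest"], signal_cfg), signal_cfg)
    vol_envs = {
        name: rectify_smooth(bandpass(rec, signal_cfg), signal_cfg)
        for name, (rec, _) in session["voluntary"].items()
    }
    calibrated = calibrate(
        rest_env, concat_envelopes(list(vol_envs.values())), signal_cfg
    )
    rest_baseline, max_level = calibrated.rest_baseline, calibrated.max_level

    seqs, labels = [], []
    for ci, name in enumerate(DIRECTIONS):
        rec, truth = session["voluntary"][name]
        feats = extract_features(rec, signal_cfg, rest_baseline, max_level)
        active = np.flatnonzero(truth["active"])
        keep = active[-TRAIN_SAMPLES:]
        wins = windows_from_features(
            feats.x[keep], network_cfg.seq_len, stride=window_stride
        )
        seqs.append(wins)
        labels.append(np.full(len(wins), ci))
    sequences = np.concatenate(seqs)
    labels = np.concatenate(labels)
    weights, report = train(
        sequences, labels, network_cfg, seed=subject_seed, max_iter=max_iter
    )

    test_seqs, test_labels = [], []
    per_class = int(np.ceil(n_heldout_windows / len(DIRECTIONS)))
    for ci, name in enumerate(DIRECTIONS):
        rec, truth = session["heldout"][name]
        feats = extract_features(rec, signal_cfg, rest_baseline, max_level)
        gated = np.flatnonzero(feats.gate & truth["active"])
        wins = windows_from_features(feats.x[gated], network_cfg.seq_len, stride=1)
        pick = np.linspace(0, len(wins) - 1, per_class).astype(int)
        test_seqs.append(wins[pick])
        test_labels.append(np.full(len(pick), ci))
    test_seqs = np.concatenate(test_seqs)[:n_heldout_windows]
    test_labels = np.concatenate(test_labels)[:n_heldout_windows]
    preds = predict_batch(test_seqs, weights, network_cfg)
    C = network_cfg.n_classes
    confusion = np.zeros((C, C), dtype=int)
    for yt, yp in zip(test_labels, preds):
        confusion[yt, yp] += 1
    return SubjectResult(
        accuracy=float(np.mean(preds == test_labels)),
        confusion=confusion,
        train_accuracy=report.final_accuracy,
        n_heldout=len(test_labels),
    )


def classifier_benchmark(
    n_subjects: int = 5,
    seed: int = 1,
    noise_sd: float = 0.1,
    **kwargs,
) -> dict:
    """Mean held-out accuracy over ``n_subjects`` simulated subjects.

    Subject seeds are derived deterministically from ``seed``. Returns
    the mean accuracy in percent plus per-subject results.
    """
    base = np.random.SeedSequence(seed)
    subject_seeds = [int(s) % (2**31) for s in base.generate_state(n_subjects)]
    results = [
        run_subject(subject_seed=s, noise_sd=noise_sd, **kwargs)
        for s in subject_seeds
    ]
    return {
        "mean_accuracy_pct": float(100.0 * np.mean([r.accuracy for r in results])),
        "per_subject": results,
        "subject_seeds": subject_seeds,
    }
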