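"""Recurrent log-linearized Gaussian-mixture network (R-LLGMN) for
motion-intent estimation from muscle-coordination sequences.

The network embeds, per motion class c, a hidden Markov model with K
states whose emission densities are M-component Gaussian mixtures. Log-
linearization replaces every product (transition probability x mixture
weight x Gaussian density) by ``exp(w^T X)`` where

    X = [1, x_1..x_L, x_i x_j for i <= j]          (H = 1 + L(L+3)/2)

is the quadratic expansion of the input — the log of a Gaussian times
nonnegative scalars is exactly a quadratic polynomial in x, so a weight
vector per unit (c, k', k, m) can represent any such model, and
training the weights directly by gradient descent sidesteps the HMM's
constrained parameterization.

Forward recursion (probability domain; the implementation works with a
per-step max-subtraction so only ratios, which are invariant to a
common positive scaling within a time step, are ever formed):

    a(c,k',k,m)(t) = exp(w(c,k',k,m)^T X(t))
    S(c,k)(t)      = sum_{k'} Q(c,k')(t-1) * sum_m a(c,k',k,m)(t)
    Q(c,k)(t)      = S(c,k)(t) / sum_{c',k''} S(c',k'')(t)
    O(c)(t)        = sum_k Q(c,k)(t)

with Q uniform at t = 0. O(c)(T) is the class posterior; the decision is
its argmax (ties broken toward the lowest class index). One reference
unit's weights are pinned at zero for identifiability.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import NetworkConfig
from .preprocess import FeatureSequence

logger = logging.getLogger(__name__)


class TrainingFailure(RuntimeError):
    """Raised when the loss becomes non-finite during optimization."""


def expand_input(x: np.ndarray) -> np.ndarray:
    """Quadratic input expansion X = [1, x, {x_i x_j, i <= j}].

    Accepts a single L-vector, a (T, L) sequence, or an (N, T, L) batch;
    the last axis is expanded from L to H = 1 + L(L+3)/2.
    """
    x = np.asarray(x, dtype=float)
    L = x.shape[-1]
    iu, ju = np.triu_indices(L)
    quad = x[..., iu] * x[..., ju]
    ones = np.ones(x.shape[:-1] + (1,))
    return np.concatenate([ones, x, quad], axis=-1)


@dataclass
class NetworkWeights:
    """Coefficients w indexed (class c, prior state k', state k, component m).

    ``w`` has shape (C, K, K, M, H). The last unit (c=C-1, k'=K-1,
    k=K-1, m=M-1) is the identifiability reference and is held at zero.
    """

    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.ndim != 5:
            raise ValueError("weights must have shape (C, K, K, M, H)")
        if not np.all(np.isfinite(self.w)):
            raise ValueError("weights must be finite")

    @property
    def shape(self) -> tuple:
        return self.w.shape


def _forward_scan(Xe: np.ndarray, w: np.ndarray, keep_cache: bool = False):
    """Run the recursion over a batch of expanded sequences.

    Xe: (N, T, H); w: (C, K, K, M, H). Returns per-time state
    probabilities Q (N, T, C, K) and, if requested, the cache needed for
    backpropagation (unit activations after max-subtraction, and the
    pre-normalization sums).
    """
    C, Kp, K, M, H = w.shape
    N, T, _ = Xe.shape
    z = np.einsum("nth,pjkmh->ntpjkm", Xe, w)  # p=class, j=prior state
    Q = np.full((N, C, K), 1.0 / (C * K))
    Q_hist = np.empty((N, T, C, K))
    a_hist = np.empty((N, T, C, Kp, K, M)) if keep_cache else None
    Z_hist = np.empty((N, T)) if keep_cache else None
    for t in range(T):
        zt = z[:, t]
        zt = zt - zt.max(axis=(1, 2, 3, 4), keepdims=True)
        a = np.exp(zt)  # (N, C, K', K, M)
        S = np.einsum("ncj,ncjkm->nck", Q, a)
        Z = S.sum(axis=(1, 2))
        if np.any(Z <= 0.0) or not np.all(np.isfinite(Z)):
            raise FloatingPointError(
                "state scores degenerated to zero; weights are pathological"
            )
        Q = S / Z[:, None, None]
        Q_hist[:, t] = Q
        if keep_cache:
            a_hist[:, t] = a
            Z_hist[:, t] = Z
    if keep_cache:
        return Q_hist, (a_hist, Z_hist)
    return Q_hist


def forward(
    seq: np.ndarray, weights: NetworkWeights, cfg: NetworkConfig
) -> np.ndarray:
    """Class posteriors O(c)(t) for one expanded or raw feature sequence.

    ``seq`` may be (T, L) raw features (expanded internally) or (T, H)
    already expanded. Returns a (T, C) array of posteriors, each row
    summing to one.
    """
    seq = np.asarray(seq, dtype=float)
    if seq.ndim != 2:
        raise ValueError("sequence must be 2-D (time x features)")
    if seq.shape[1] == cfg.input_dim:
        seq = expand_input(seq)
    elif seq.shape[1] != cfg.expanded_dim:
        raise ValueError(
            f"feature dimension {seq.shape[1]} matches neither input_dim "
            f"{cfg.input_dim} nor expanded_dim {cfg.expanded_dim}"
        )
    Q_hist = _forward_scan(seq[None], weights.w)
    return Q_hist[0].sum(axis=-1)


def classify(posteriors: np.ndarray) -> int:
    """Decision from a posterior sequence: argmax at the final time.

    Ties break toward the lowest class index.
    """
    posteriors = np.atleast_2d(np.asarray(posteriors))
    if posteriors.size == 0:
        raise ValueError("empty posterior sequence")
    return int(np.argmax(posteriors[-1]))


def _loss_and_grad(
    Xe: np.ndarray, labels: np.ndarray, w: np.ndarray
) -> tuple[float, np.ndarray]:
    """Negative log-likelihood J = -sum_n log O(c_n)(T) and dJ/dw.

    Reverse-mode differentiation through the normalized recursion. The
    per-step max-subtraction needs no gradient: the loss is invariant to
    a common shift of all unit pre-activations within a time step, so
    treating the subtracted maximum as a constant yields the exact
    gradient.
    """
    C, Kp, K, M, H = w.shape
    N, T, _ = Xe.shape
    Q_hist, (a_hist, Z_hist) = _forward_scan(Xe, w, keep_cache=True)
    O_final = Q_hist[:, -1].sum(axis=-1)  # (N, C)
    p_true = O_final[np.arange(N), labels]
    if np.any(p_true < 1e-300):
        raise TrainingFailure("posterior of a training label underflowed")
    loss = -np.sum(np.log(p_true))
    if not np.isfinite(loss):
        raise TrainingFailure("non-finite loss encountered")

    grad = np.zeros_like(w)
    gQ = np.zeros((N, C, K))
    gQ[np.arange(N), labels, :] = -1.0 / p_true[:, None]
    Q0 = np.full((N, C, K), 1.0 / (C * K))
    for t in range(T - 1, -1, -1):
        Qt = Q_hist[:, t]
        Zt = Z_hist[:, t]
        inner = np.einsum("nck,nck->n", gQ, Qt)
        gS = (gQ - inner[:, None, None]) / Zt[:, None, None]
        Qprev = Q_hist[:, t - 1] if t > 0 else Q0
        at = a_hist[:, t]
        # dJ/dz(c,k',k,m,t) = gS(c,k) * Qprev(c,k') * a(c,k',k,m)
        gz = gS[:, :, None, :, None] * Qprev[:, :, :, None, None] * at
        grad += np.einsum("ncjkm,nh->cjkmh", gz, Xe[:, t])
        gQ = np.einsum("nck,ncjkm->ncj", gS, at)
    grad[-1, -1, -1, -1, :] = 0.0  # reference unit stays pinned
    return loss, grad


@dataclass
class TrainingReport:
    """Optimization diagnostics returned by :func:`train`."""

    loss_curve: list = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    final_accuracy: float = float("nan")
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "loss_curve": [float(v) for v in self.loss_curve],
            "n_iter": self.n_iter,
            "converged": self.converged,
            "final_accuracy": self.final_accuracy,
            "seed": self.seed,
        }


def train(
    sequences: np.ndarray,
    labels: np.ndarray,
    cfg: NetworkConfig,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-8,
    init_sigma: float = 0.01,
) -> tuple[NetworkWeights, TrainingReport]:
    """Fit the network by full-batch gradient descent.

    Parameters
    ----------
    sequences : ndarray, shape (N, T, L)
        Labeled feature windows of length ``cfg.seq_len``.
    labels : ndarray of int, shape (N,)
        Class indices in ``0 .. n_classes-1``; every class must appear.
    seed : int
        Seeds the Gaussian weight initialization; identical data and
        seed reproduce identical weights bit for bit.
    max_iter, tol : int, float
        Iteration cap and relative-loss-change stopping criterion for
        the descent with backtracking (Armijo) line search.
    """
    sequences = np.asarray(sequences, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if sequences.ndim != 3 or sequences.shape[0] != labels.shape[0]:
        raise ValueError("sequences must be (N, T, L) matching labels (N,)")
    if sequences.shape[1] != cfg.seq_len:
        raise ValueError(
            f"window length {sequences.shape[1]} != cfg.seq_len {cfg.seq_len}"
        )
    present = np.unique(labels)
    if not np.array_equal(present, np.arange(cfg.n_classes)) and not (
        present.min() >= 0 and present.max() < cfg.n_classes
    ):
        raise ValueError("labels outside 0..n_classes-1")
    missing = set(range(cfg.n_classes)) - set(present.tolist())
    if missing:
        raise ValueError(f"classes {sorted(missing)} absent from training set")

    C, K, M = cfg.n_classes, cfg.n_states, cfg.n_components
    H = cfg.expanded_dim
    rng = np.random.default_rng(seed)
    w = rng.normal(0.0, init_sigma, size=(C, K, K, M, H))
    w[-1, -1, -1, -1, :] = 0.0

    Xe = expand_input(sequences)
    report = TrainingReport(seed=seed)
    loss, grad = _loss_and_grad(Xe, labels, w)
    report.loss_curve.append(loss)
    step = 1.0
    for it in range(max_iter):
        gnorm2 = float(np.sum(grad * grad))
        if gnorm2 == 0.0:
            report.converged = True
            break
        # Armijo backtracking along the steepest-descent direction
        new_loss, new_grad = loss, grad
        accepted = False
        for _ in range(40):
            w_trial = w - step * grad
            w_trial[-1, -1, -1, -1, :] = 0.0
            try:
                with np.errstate(divide="ignore"):
                    new_loss, new_grad = _loss_and_grad(Xe, labels, w_trial)
            except (FloatingPointError, TrainingFailure):
                # overshoot collapsed a posterior to zero; shrink the step
                step *= 0.5
                continue
            if new_loss <= loss - 1e-4 * step * gnorm2:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            report.converged = True  # no descent step exists at float precision
            break
        w = w_trial
        rel_change = abs(loss - new_loss) / max(abs(loss), 1.0)
        loss, grad = new_loss, new_grad
        report.loss_curve.append(loss)
        step = min(step * 2.0, 1e6)
        if rel_change < tol:
            report.converged = True
            break
    report.n_iter = len(report.loss_curve) - 1

    weights = NetworkWeights(w)
    preds = predict_batch(sequences, weights, cfg)
    report.final_accuracy = float(np.mean(preds == labels))
    return weights, report


def predict_batch(
    sequences: np.ndarray, weights: NetworkWeights, cfg: NetworkConfig
) -> np.ndarray:
    """Vectorized decisions for a batch of (N, T, L) feature windows."""
    Xe = expand_input(np.asarray(sequences, dtype=float))
    Q_hist = _forward_scan(Xe, weights.w)
    O_final = Q_hist[:, -1].sum(axis=-1)
    return np.argmax(O_final, axis=1)


@dataclass
class DecisionEvent:
    """One motion-intent decision emitted at a gate onset."""

    time: float
    class_id: int
    posterior: np.ndarray


def estimate_motion(
    features: FeatureSequence,
    weights: NetworkWeights,
    cfg: NetworkConfig,
) -> list[DecisionEvent]:
    """Scan a gated feature stream and emit one decision per activation.

    When the gate turns true, the trailing ``cfg.seq_len`` samples are
    classified and a single event is emitted; no further events occur
    until the gate falls again. A gate onset before ``seq_len`` samples
    exist defers the decision until enough history has accumulated
    (logged as a warning), provided the gate is still open.
    """
    events: list[DecisionEvent] = []
    g = np.asarray(features.gate, dtype=bool)
    n = len(g)
    armed = True  # gate must drop before the next event
    pending = False
    for i in range(n):
        if not g[i]:
            armed = True
            pending = False
            continue
        onset = g[i] and (i == 0 or not g[i - 1])
        if onset and armed:
            if i + 1 < cfg.seq_len:
                logger.warning(
                    "gate onset at sample %d before %d samples exist; "
                    "decision deferred", i, cfg.seq_len
                )
                pending = True
                continue
            pending = False
        elif pending and i + 1 >= cfg.seq_len:
            pending = False
        else:
            continue
        window = features.x[i + 1 - cfg.seq_len : i + 1]
        post = forward(window, weights, cfg)
        events.append(
            DecisionEvent(time=float(features.t[i]), class_id=classify(post),
                          posterior=post[-1])
        )
        armed = False
    if pending:
        warnings.warn("activation ended before a full decision window existed")
    return events


def windows_from_features(
    x: np.ndarray, seq_len: int, stride: int = 1
) -> np.ndarray:
    """Slice a (T, L) feature series into (N, seq_len, L) training windows."""
    x = np.asarray(x, dtype=float)
    T = x.shape[0]
    if T < seq_len:
        raise ValueError(f"series of length {T} shorter than window {seq_len}")
    starts = np.arange(0, T - seq_len + 1, stride)
    return np.stack([x[s : s + seq_len] for s in starts])
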