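"""Recurrent probabilistic network: expansion, forward recursion against
an independent HMM forward-algorithm oracle, training, and decisions."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from emghybrid.classifier import (NetworkWeights, _loss_and_grad,
                                  classify, estimate_motion, expand_input,
                                  forward, train,
                                  windows_from_features)
from emghybrid.config import NetworkConfig
from emghybrid.preprocess import FeatureSequence


class TestExpandInput:
    def test_expanded_dimension_four_channels(self):
        assert expand_input(np.zeros(4)).shape == (15,)
        assert NetworkConfig(input_dim=4).expanded_dim == 15

    def test_zero_input_is_bias_only(self):
        X = expand_input(np.zeros(4))
        assert X[0] == 1.0 and np.all(X[1:] == 0.0)

    def test_one_channel_monomials(self):
        a = 0.7
        assert np.allclose(expand_input(np.array([a])), [1.0, a, a * a])


def _loglinearize(A, rho, means, covs, H):
    """Map a per-class Gaussian-mixture HMM onto the network's weights.

    log(transition x mixture weight x Gaussian density) is a quadratic
    polynomial in x, i.e. exactly representable in the expanded basis.
    """
    C = len(A)
    K, M, L = means[0].shape
    iu, ju = np.triu_indices(L)
    w = np.zeros((C, K, K, M, H))
    for c in range(C):
        for kp in range(K):
            for k in range(K):
                for m in range(M):
                    lam = np.linalg.inv(covs[c][k, m])
                    mu = means[c][k, m]
                    bias = (
                        np.log(A[c][kp, k]) + np.log(rho[c][k, m])
                        - 0.5 * mu @ lam @ mu
                        - 0.5 * np.log(np.linalg.det(covs[c][k, m]))
                        - 0.5 * L * np.log(2 * np.pi)
                    )
                    quad = np.where(iu == ju, -0.5 * lam[iu, ju], -lam[iu, ju])
                    w[c, kp, k, m] = np.concatenate([[bias], lam @ mu, quad])
    return NetworkWeights(w)


def _random_gmm_hmm(rng, C=2, K=2, M=2, L=2):
    A, rho, means, covs = [], [], [], []
    for _ in range(C):
        a = rng.uniform(0.2, 1.0, (K, K))
        A.append(a / a.sum(axis=1, keepdims=True))
        r = rng.uniform(0.2, 1.0, (K, M))
        rho.append(r / r.sum(axis=1, keepdims=True))
        means.append(rng.normal(0.0, 1.0, (K, M, L)))
        cv = np.zeros((K, M, L, L))
        for k in range(K):
            for m in range(M):
                B = rng.normal(0.0, 0.5, (L, L))
                cv[k, m] = B @ B.T + 0.3 * np.eye(L)
        covs.append(cv)
    return A, rho, means, covs


def _oracle_posterior(x, A, rho, means, covs):
    """Direct probability-domain forward algorithm across classes."""
    C, (K, M, L) = len(A), means[0].shape
    alpha = np.full((C, K), 1.0 / (C * K))
    for t in range(len(x)):
        new = np.zeros((C, K))
        for c in range(C):
            for k in range(K):
                emit = sum(
                    rho[c][k, m]
                    * multivariate_normal.pdf(x[t], means[c][k, m], covs[c][k, m])
                    for m in range(M)
                )
                new[c, k] = sum(alpha[c, kp] * A[c][kp, k] for kp in range(K)) * emit
        alpha = new / new.sum()
    return alpha.sum(axis=1)


class TestForward:
    def test_identical_classes_give_uniform_posterior(self, small_net_cfg, rng):
        C, K, M, H = 2, 2, 2, small_net_cfg.expanded_dim
        w = np.tile(rng.normal(0, 0.3, (1, K, K, M, H)), (C, 1, 1, 1, 1))
        post = forward(rng.normal(0, 1, (10, 2)), NetworkWeights(w), small_net_cfg)
        assert np.allclose(post, 0.5, atol=1e-12)

    def test_posteriors_normalized_at_every_step(self, small_net_cfg, rng):
        w = NetworkWeights(rng.normal(0, 0.5, (2, 2, 2, 2, small_net_cfg.expanded_dim)))
        post = forward(rng.normal(0, 1, (25, 2)), w, small_net_cfg)
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)
        assert np.all((post >= 0) & (post <= 1))

    def test_matches_hmm_forward_oracle(self, small_net_cfg, rng):
        """Log-linearized GMM-HMM weights reproduce the Bayes posterior."""
        A, rho, means, covs = _random_gmm_hmm(rng)
        w = _loglinearize(A, rho, means, covs, small_net_cfg.expanded_dim)
        worst = 0.0
        for _ in range(100):
            x = rng.normal(0.0, 1.0, (small_net_cfg.seq_len, 2))
            post = forward(x, w, small_net_cfg)[-1]
            worst = max(worst, np.abs(post - _oracle_posterior(x, A, rho, means, covs)).max())
        assert worst < 1e-6

    def test_matches_hmmlearn_likelihoods(self, small_net_cfg, rng):
        """Cross-check class posteriors against hmmlearn per-class scores."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        A, rho, means, covs = _random_gmm_hmm(rng)
        w = _loglinearize(A, rho, means, covs, small_net_cfg.expanded_dim)
        x = rng.normal(0.0, 1.0, (small_net_cfg.seq_len, 2))
        logls = []
        for c in range(2):
            model = hmmlearn.GMMHMM(n_components=2, n_mix=2,
                                    covariance_type="full", init_params="")
            # uniform state prior at t=0 maps to this effective start prob
            model.startprob_ = A[c].mean(axis=0)
            model.transmat_ = A[c]
            model.weights_ = rho[c]
            model.means_ = means[c]
            model.covars_ = covs[c]
            logls.append(model.score(x))
        expected = np.exp(logls - np.max(logls))
        expected /= expected.sum()
        post = forward(x, w, small_net_cfg)[-1]
        assert np.allclose(post, expected, atol=1e-6)

    def test_scaling_invariance_within_time_step(self, small_net_cfg, rng):
        """A common bias shift (scaling every activation) changes nothing."""
        w = rng.normal(0, 0.5, (2, 2, 2, 2, small_net_cfg.expanded_dim))
        shifted = w.copy()
        shifted[..., 0] += 3.7  # scales every unit by e^3.7 at each step
        x = rng.normal(0, 1, (10, 2))
        p1 = forward(x, NetworkWeights(w), small_net_cfg)
        p2 = forward(x, NetworkWeights(shifted), small_net_cfg)
        assert np.allclose(p1, p2, atol=1e-9)


class TestGradient:
    def test_analytic_gradient_matches_finite_differences(self, small_net_cfg, rng):
        H = small_net_cfg.expanded_dim
        Xe = expand_input(rng.normal(0, 0.5, (6, small_net_cfg.seq_len, 2)))
        labels = np.array([0, 1, 0, 1, 0, 1])
        w = rng.normal(0, 0.05, (2, 2, 2, 2, H))
        w[-1, -1, -1, -1] = 0.0
        loss, grad = _loss_and_grad(Xe, labels, w)
        eps = 1e-6
        idx_rng = np.random.default_rng(0)
        for _ in range(8):
            idx = tuple(idx_rng.integers(0, s) for s in w.shape)
            wp, wm = w.copy(), w.copy()
            wp[idx] += eps
            wm[idx] -= eps
            num = (_loss_and_grad(Xe, labels, wp)[0]
                   - _loss_and_grad(Xe, labels, wm)[0]) / (2 * eps)
            if idx[:4] == (1, 1, 1, 1):  # pinned reference unit
                assert grad[idx] == 0.0
            else:
                assert grad[idx] == pytest.approx(num, rel=1e-5, abs=1e-8)


def _two_class_windows(rng, n_per_class=30, T=10, noise=0.02):
    """Well-separated coordination sequences around two disjoint patterns."""
    patterns = np.array([[0.8, 0.2], [0.2, 0.8]])
    seqs, labels = [], []
    for c, p in enumerate(patterns):
        x = p[None, None, :] + noise * rng.standard_normal((n_per_class, T, 2))
        seqs.append(np.clip(x, 1e-3, None))
        labels.append(np.full(n_per_class, c))
    return np.concatenate(seqs), np.concatenate(labels), patterns


class TestTrain:
    def test_separable_classes_reach_perfect_accuracy(self, small_net_cfg, rng):
        seqs, labels, patterns = _two_class_windows(rng)
        # nearest-centroid oracle confirms the data are separable first
        centroids = np.array([seqs[labels == c].mean(axis=(0, 1)) for c in (0, 1)])
        nc = np.argmin(
            np.linalg.norm(seqs.mean(axis=1)[:, None, :] - centroids[None], axis=2),
            axis=1,
        )
        assert np.mean(nc == labels) == 1.0
        weights, report = train(seqs, labels, small_net_cfg, seed=0, max_iter=200)
        assert report.final_accuracy == 1.0

    def test_single_class_degenerates_to_certainty(self, rng):
        cfg = NetworkConfig(n_classes=1, n_states=2, n_components=2,
                            seq_len=10, input_dim=2)
        seqs = rng.uniform(0.2, 0.8, (5, 10, 2))
        weights, report = train(seqs, np.zeros(5, dtype=int), cfg, seed=0,
                                max_iter=50)
        post = forward(seqs[0], weights, cfg)
        assert np.allclose(post, 1.0)
        assert report.loss_curve[-1] == pytest.approx(0.0, abs=1e-12)

    def test_same_seed_reproduces_weights_bitwise(self, small_net_cfg, rng):
        seqs, labels, _ = _two_class_windows(rng, n_per_class=10)
        w1, _ = train(seqs, labels, small_net_cfg, seed=7, max_iter=30)
        w2, _ = train(seqs, labels, small_net_cfg, seed=7, max_iter=30)
        assert np.array_equal(w1.w, w2.w)

    def test_missing_class_rejected(self, small_net_cfg, rng):
        seqs = rng.uniform(0.2, 0.8, (4, 10, 2))
        with pytest.raises(ValueError, match="absent"):
            train(seqs, np.zeros(4, dtype=int), small_net_cfg)


class TestClassify:
    def test_argmax_of_final_posterior(self):
        assert classify(np.array([[0.1, 0.7, 0.1, 0.1]])) == 1

    def test_tie_breaks_to_lowest_index(self):
        assert classify(np.array([[0.5, 0.5]])) == 0

    def test_oracle_constructed_sequence(self, small_net_cfg, rng):
        A, rho, means, covs = _random_gmm_hmm(rng)
        w = _loglinearize(A, rho, means, covs, small_net_cfg.expanded_dim)
        # sample straight from class 1's HMM emission mixture
        x = means[1][0, 0] + 0.1 * rng.standard_normal((small_net_cfg.seq_len, 2))
        post = forward(x, w, small_net_cfg)
        oracle = _oracle_posterior(x, A, rho, means, covs)
        assert classify(post) == int(np.argmax(oracle))


def _feature_stream(gate_mask, pattern, T, rng):
    n = len(gate_mask)
    x = pattern[None, :] + 0.02 * rng.standard_normal((n, 2))
    return FeatureSequence(
        t=np.arange(n) / 1000.0, x=np.clip(x, 1e-3, None),
        activation=np.where(gate_mask, 0.5, 0.0), gate=np.asarray(gate_mask),
        subthreshold=np.zeros(n, dtype=bool),
    )


class TestEstimateMotion:
    @pytest.fixture
    def trained(self, small_net_cfg, rng):
        seqs, labels, patterns = _two_class_windows(rng)
        weights, _ = train(seqs, labels, small_net_cfg, seed=0, max_iter=200)
        return weights, patterns

    def test_no_gate_no_events(self, small_net_cfg, trained, rng):
        weights, patterns = trained
        feats = _feature_stream(np.zeros(200, dtype=bool), patterns[0],
                                small_net_cfg.seq_len, rng)
        assert estimate_motion(feats, weights, small_net_cfg) == []

    def test_single_sustained_activation_single_event(self, small_net_cfg,
                                                      trained, rng):
        weights, patterns = trained
        g = np.zeros(300, dtype=bool)
        g[100:250] = True
        feats = _feature_stream(g, patterns[1], small_net_cfg.seq_len, rng)
        events = estimate_motion(feats, weights, small_net_cfg)
        assert len(events) == 1
        assert events[0].class_id == 1
        assert events[0].time == pytest.approx(0.100)

    def test_two_separated_activations_two_events(self, small_net_cfg,
                                                  trained, rng):
        weights, patterns = trained
        g = np.zeros(400, dtype=bool)
        g[100:180] = True
        g[250:350] = True
        feats = _feature_stream(g, patterns[0], small_net_cfg.seq_len, rng)
        events = estimate_motion(feats, weights, small_net_cfg)
        assert len(events) == 2
        assert all(ev.class_id == 0 for ev in events)

    def test_early_onset_deferred_until_window_exists(self, small_net_cfg,
                                                      trained, rng):
        weights, patterns = trained
        g = np.zeros(100, dtype=bool)
        g[2:80] = True  # onset at sample 2, before seq_len samples exist
        feats = _feature_stream(g, patterns[0], small_net_cfg.seq_len, rng)
        events = estimate_motion(feats, weights, small_net_cfg)
        assert len(events) == 1
        assert events[0].time >= (small_net_cfg.seq_len - 1) / 1000.0


class TestWindows:
    def test_stride_and_count(self, rng):
        x = rng.normal(size=(500, 4))
        wins = windows_from_features(x, 50, stride=1)
        assert wins.shape == (451, 50, 4)
        assert windows_from_features(x, 50, stride=50).shape == (10, 50, 4)
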