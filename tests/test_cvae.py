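"""Conditional VAE: posterior/decoder contracts, ELBO identities against a
Monte-Carlo oracle, gradient correctness, training and classification."""

import numpy as np
import pytest

from hybridpath import cvae as cv
from hybridpath.cvae import (
    CVAEConfig,
    LatentPosterior,
    classify,
    decode,
    elbo_loss,
    encode,
    train,
    tune_hyperparams,
)


def _toy_dataset(n=400, effect=3.0, seed=0):
    rng = np.random.default_rng(seed)
    y = (np.arange(n) >= n // 2).astype(int)
    X = rng.normal(0, 1, (n, 33))
    X[y == 1, :8] += effect
    lo, hi = cv.fit_minmax(X)
    Xs = cv.apply_minmax(X, lo, hi)
    perm = rng.permutation(n)
    return Xs[perm], y[perm]


class TestEncodeDecode:
    def test_zero_weights_give_standard_normal_posterior(self):
        params = cv.init_params(seed=0)
        for k in params.weights:
            params.weights[k] = np.zeros_like(params.weights[k])
        post = encode(np.full(33, 0.3), params)
        np.testing.assert_array_equal(post.mean, 0.0)
        np.testing.assert_array_equal(post.logvar, 0.0)

    def test_zero_weights_decode_to_half(self):
        params = cv.init_params(seed=0)
        for k in params.weights:
            params.weights[k] = np.zeros_like(params.weights[k])
        recon = decode(np.zeros(params.config.z_dim), "benign", params)
        np.testing.assert_allclose(recon, 0.5)

    def test_posterior_deterministic(self):
        params = cv.init_params(seed=1)
        x = np.random.default_rng(2).random(33)
        a, b = encode(x, params), encode(x, params)
        np.testing.assert_array_equal(a.mean, b.mean)

    def test_decoder_output_in_open_unit_interval(self, rng):
        params = cv.init_params(seed=3)
        for _ in range(50):
            r = decode(rng.normal(size=params.config.z_dim), "malignant", params)
            assert (r > 0).all() and (r < 1).all()

    def test_unknown_label_rejected(self):
        params = cv.init_params(seed=0)
        with pytest.raises(ValueError):
            decode(np.zeros(params.config.z_dim), "unknown", params)

    def test_encoder_finite_on_fuzz(self, rng):
        params = cv.init_params(seed=4)
        X = rng.random((1000, 33))
        post = encode(X, params)
        assert np.all(np.isfinite(post.mean)) and np.all(np.isfinite(post.logvar))


class TestELBO:
    def test_standard_normal_posterior_has_zero_kl(self):
        post = LatentPosterior(mean=np.zeros(4), logvar=np.zeros(4))
        b = elbo_loss(np.full(33, 0.5), np.full(33, 0.5), post)
        assert b.kl == pytest.approx(0.0)

    def test_unit_mean_shift_kl_is_half(self):
        post = LatentPosterior(mean=np.array([1.0]), logvar=np.array([0.0]))
        b = elbo_loss(np.full(33, 0.5), np.full(33, 0.5), post)
        assert b.kl == pytest.approx(0.5)

    def test_total_is_recon_plus_kl(self, rng):
        post = LatentPosterior(mean=rng.normal(size=6), logvar=rng.normal(size=6))
        x = rng.random(33)
        r = np.clip(rng.random(33), 0.01, 0.99)
        b = elbo_loss(x, r, post)
        assert b.total == pytest.approx(b.recon + b.kl, abs=1e-9)
        assert b.kl >= 0

    def test_kl_matches_monte_carlo_oracle(self, rng):
        """Closed form vs a 10⁵-sample estimate of E_q[log q − log p]."""
        mu = rng.normal(size=3)
        logvar = rng.normal(size=3) * 0.5
        sd = np.exp(0.5 * logvar)
        z = mu + sd * rng.standard_normal((100_000, 3))
        log_q = (-0.5 * np.log(2 * np.pi) - 0.5 * logvar
                 - 0.5 * ((z - mu) / sd) ** 2).sum(axis=1)
        log_p = (-0.5 * np.log(2 * np.pi) - 0.5 * z ** 2).sum(axis=1)
        mc = float(np.mean(log_q - log_p))
        post = LatentPosterior(mean=mu, logvar=logvar)
        b = elbo_loss(np.full(33, 0.5), np.full(33, 0.5), post)
        assert b.kl == pytest.approx(mc, rel=0.01)

    def test_out_of_range_reconstruction_rejected(self):
        post = LatentPosterior(mean=np.zeros(2), logvar=np.zeros(2))
        with pytest.raises(ValueError):
            elbo_loss(np.full(33, 0.5), np.full(33, 1.0), post)


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        """Hand-derived gradients vs central differences on a tiny network."""
        cfg = CVAEConfig(h1=5, h2=4, z_dim=3)
        params = cv.init_params(cfg, seed=7)
        w = params.weights
        X = rng.random((6, 33))
        onehot = cv._one_hot(rng.integers(0, 2, 6))
        eps = rng.standard_normal((6, 3))
        grads, _, _ = cv._forward_backward(w, X, onehot, eps)

        def loss_at(wmod):
            _, rec, kl = cv._forward_backward(wmod, X, onehot, eps)
            return rec + kl

        h = 1e-6
        for key in ("We1", "Wmu", "Wlv", "Wd2", "bd3"):
            flat_idx = [(0, 0), (1, 2)] if w[key].ndim == 2 else [(0,), (1,)]
            for idx in flat_idx:
                wp = {k: v.copy() for k, v in w.items()}
                wp[key][idx] += h
                wm = {k: v.copy() for k, v in w.items()}
                wm[key][idx] -= h
                num = (loss_at(wp) - loss_at(wm)) / (2 * h)
                assert grads[key][idx] == pytest.approx(num, rel=1e-4, abs=1e-7)


class TestTraining:
    def test_zero_learning_rate_freezes_params(self):
        X, y = _toy_dataset(n=64)
        cfg = CVAEConfig(learning_rate=0.0, epochs=3)
        params, _ = train(X, y, cfg, seed=0)
        init = cv.init_params(cfg, seed=0)
        for k in init.weights:
            np.testing.assert_array_equal(params.weights[k], init.weights[k])

    def test_loss_trend_non_increasing(self):
        X, y = _toy_dataset(n=400)
        _, hist = train(X, y, CVAEConfig(epochs=120), seed=1)
        ma = np.convolve(hist["total"], np.ones(20) / 20, mode="valid")
        assert np.all(np.diff(ma) <= 1e-3)
        assert ma[-1] < ma[0]

    def test_seeded_determinism(self):
        X, y = _toy_dataset(n=96)
        cfg = CVAEConfig(epochs=10)
        _, h1 = train(X, y, cfg, seed=5)
        _, h2 = train(X, y, cfg, seed=5)
        assert h1["total"][-1] == h2["total"][-1]

    def test_unscaled_input_rejected(self):
        X, y = _toy_dataset(n=64)
        with pytest.raises(ValueError):
            train(X * 300.0, y, CVAEConfig(epochs=1), seed=0)


@pytest.fixture(scope="module")
def trained():
    X, y = _toy_dataset(n=1000, effect=3.0, seed=3)
    params, _ = train(X[:700], y[:700], CVAEConfig(epochs=150), seed=3)
    return params, X[700:], y[700:]


class TestClassification:

    def test_accuracy_on_separated_classes(self, trained):
        params, Xte, yte = trained
        pred = cv.classify_batch(Xte, params)
        assert np.mean(pred == yte) >= 0.95

    def test_single_sample_scores_both_labels(self, trained):
        params, Xte, _ = trained
        label, scores = classify(Xte[0], params)
        assert label in ("benign", "malignant")
        assert set(scores) == {"benign", "malignant"}
        assert all(np.isfinite(v) for v in scores.values())

    def test_untrained_params_rejected(self):
        params = cv.init_params(seed=0)
        with pytest.raises(ValueError):
            classify(np.full(33, 0.5), params)


class TestTuning:
    def test_singleton_space_returns_that_point(self):
        X, y = _toy_dataset(n=64)
        space = {"log10_lr": (-2.0, -2.0), "z_dim": (4, 4),
                 "h1": (16, 16), "h2": (8, 8)}
        cfg = tune_hyperparams((X[:48], y[:48]), (X[48:], y[48:]), space,
                               tune_epochs=2, pop_size=2, t_max=1, seed=0)
        assert (cfg.learning_rate, cfg.z_dim, cfg.h1, cfg.h2) == (0.01, 4, 16, 8)

    def test_empty_space_rejected(self):
        X, y = _toy_dataset(n=64)
        with pytest.raises(ValueError):
            tune_hyperparams((X, y), (X, y), {})

    def test_reproducible_under_seed(self):
        X, y = _toy_dataset(n=64)
        space = {"log10_lr": (-2.5, -1.5), "z_dim": (2, 8)}
        a = tune_hyperparams((X[:48], y[:48]), (X[48:], y[48:]), space,
                             tune_epochs=2, pop_size=3, t_max=2, seed=4)
        b = tune_hyperparams((X[:48], y[:48]), (X[48:], y[48:]), space,
                             tune_epochs=2, pop_size=3, t_max=2, seed=4)
        assert a == b


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        X, y = _toy_dataset(n=64)
        params, _ = train(X, y, CVAEConfig(epochs=5), seed=2)
        params.x_min = np.zeros(33)
        params.x_max = np.ones(33)
        path = tmp_path / "model.npz"
        cv.save_params(params, path)
        back = cv.load_params(path)
        assert back.trained
        pred_a = cv.classify_batch(X[:10], params)
        pred_b = cv.classify_batch(X[:10], back)
        np.testing.assert_array_equal(pred_a, pred_b)
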