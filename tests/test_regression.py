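"""PLSR, the LM-trained BP network, SSA and their composition."""

import numpy as np
import pytest

from agarispec import (
    BpConfig, SsaConfig, bp_predict, bp_scan_hidden, bp_train, plsr_fit,
    plsr_predict, plsr_select_k, r2_score, ssa_bp_train, ssa_optimize,
)
from agarispec.neural import _first_argmax


class TestPlsr:
    def test_exact_recovery_on_noiseless_linear_data(self, rng):
        X = rng.normal(size=(30, 8))
        y = X @ rng.normal(size=8) + 2.0
        model = plsr_fit(X, y, k=8)
        assert np.sqrt(np.mean((plsr_predict(model, X) - y) ** 2)) < 1e-8

    def test_full_rank_equals_ols(self, rng):
        """With orthonormal centered columns, PLS at k=p collapses to OLS."""
        A = rng.normal(size=(40, 10))
        A -= A.mean(axis=0)
        Q, _ = np.linalg.qr(A)
        y = Q @ rng.normal(size=10) + rng.normal(0, 0.1, 40)
        model = plsr_fit(Q, y, k=10)
        ols = np.linalg.lstsq(np.column_stack([np.ones(40), Q]), y, rcond=None)[0]
        assert np.max(np.abs(model.coefficients - ols[1:])) < 1e-8

    def test_first_factor_matches_power_iteration_oracle(self, rng):
        X = rng.normal(size=(25, 6))
        y = X[:, 0] + 0.5 * X[:, 3] + rng.normal(0, 0.05, 25)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        w = Xc.T @ yc
        w /= np.linalg.norm(w)
        t = Xc @ w
        pred_oracle = y.mean() + t * (t @ yc) / (t @ t)
        model = plsr_fit(X, y, k=1)
        assert np.max(np.abs(plsr_predict(model, X) - pred_oracle)) < 1e-8

    def test_factor_and_coefficient_paths_agree(self, rng):
        X = rng.normal(size=(30, 12))
        y = rng.normal(size=30)
        model = plsr_fit(X, y, k=4)
        a = plsr_predict(model, X)
        b = plsr_predict(model, X, via_factors=True)
        assert np.max(np.abs(a - b)) < 1e-8

    def test_select_k_finds_informative_rank(self, rng):
        latent = rng.normal(size=(60, 3))
        X = latent @ rng.normal(size=(3, 20)) + rng.normal(0, 0.01, (60, 20))
        y = latent @ np.array([1.0, -2.0, 0.5])
        k, curve = plsr_select_k(X, y, k_max=10, seed=0)
        model = plsr_fit(X, y, k)
        assert r2_score(y, plsr_predict(model, X)) > 0.999
        assert curve.shape == (10,)

    def test_invalid_inputs_rejected(self, rng):
        X = rng.normal(size=(10, 5))
        with pytest.raises(ValueError):
            plsr_fit(X, rng.normal(size=10), k=10)
        with pytest.raises(ValueError, match="zero-variance"):
            plsr_fit(X, np.ones(10), k=2)


class TestBp:
    def test_constant_target_converges_to_bias(self, rng):
        X = rng.normal(size=(40, 3))
        y = np.full(40, 7.5)
        model = bp_train(X, y, BpConfig(n_hidden=5, seed=1, goal_mse=1e-9))
        assert np.mean((bp_predict(model, X) - y) ** 2) < 1e-6

    def test_sine_benchmark(self):
        x = np.linspace(0, 2 * np.pi, 200)[:, None]
        y = np.sin(x).ravel()
        model = bp_train(x, y, BpConfig(n_hidden=8, max_epochs=100, seed=0,
                                        val_fraction=0.0))
        assert r2_score(y, bp_predict(model, x)) > 0.99

    def test_training_is_deterministic(self, rng):
        X = rng.normal(size=(50, 4))
        y = X @ np.ones(4) + rng.normal(0, 0.1, 50)
        m1 = bp_train(X, y, BpConfig(seed=3))
        m2 = bp_train(X, y, BpConfig(seed=3))
        assert np.array_equal(m1.W1, m2.W1) and np.array_equal(m1.w2, m2.w2)
        assert m1.history == m2.history

    def test_predict_is_pure(self, rng):
        X = rng.normal(size=(30, 2))
        model = bp_train(X, X.sum(axis=1), BpConfig(seed=0))
        assert np.array_equal(bp_predict(model, X), bp_predict(model, X))

    def test_bad_theta0_rejected(self, rng):
        X = rng.normal(size=(20, 2))
        with pytest.raises(ValueError, match="theta0"):
            bp_train(X, X.sum(axis=1), BpConfig(n_hidden=5), theta0=np.ones(3))

    def test_history_tracks_training_mse(self, rng):
        X = rng.normal(size=(30, 2))
        model = bp_train(X, X.sum(axis=1), BpConfig(seed=0, val_fraction=0.0))
        epochs, mses = zip(*model.history)
        assert epochs[0] == 0
        assert np.all(np.diff(mses) <= 1e-15)  # pure LM descent never increases


class TestScanHidden:
    def test_tie_break_prefers_smallest(self):
        assert _first_argmax([1.0, 1.0, 0.5]) == 0
        assert _first_argmax([0.2, 0.9, 0.9]) == 1

    def test_linear_target_all_sizes_good(self, rng):
        X = rng.normal(size=(80, 3))
        y = X @ np.array([1.0, -1.0, 0.5])
        model, scores = bp_scan_hidden(X, y, config=BpConfig(seed=2))
        assert set(scores) == set(range(5, 11))
        assert all(s > 0.95 for s in scores.values())
        assert 5 <= model.config.n_hidden <= 10
        assert r2_score(y, bp_predict(model, X)) > 0.95


class TestSsa:
    def test_sphere_function_median(self):
        vals = []
        for seed in range(20):
            _, f, _ = ssa_optimize(lambda v: float(v @ v), 5, (-5, 5),
                                   SsaConfig(seed=seed))
            vals.append(f)
        assert np.median(vals) < 1e-2

    def test_history_monotone_and_in_bounds(self):
        x, f, hist = ssa_optimize(lambda v: float(np.sum((v - 2) ** 2)), 3,
                                  (-4, 4), SsaConfig(seed=5))
        assert np.all(np.diff(hist) <= 0)
        assert hist.size == 21
        assert np.all(x >= -4) and np.all(x <= 4)
        assert hist[-1] == pytest.approx(f)

    def test_non_finite_fitness_reported(self):
        with pytest.raises(ValueError, match="non-finite fitness"):
            ssa_optimize(lambda v: np.nan, 2, (-1, 1), SsaConfig(seed=0))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SsaConfig(pop_size=1)
        with pytest.raises(ValueError):
            SsaConfig(alert_value=0.0)


class TestSsaBp:
    def test_zero_iterations_degenerates_to_plain_training(self, rng):
        X = rng.normal(size=(60, 3))
        y = X @ np.ones(3) + rng.normal(0, 0.2, 60)
        cfg = BpConfig(n_hidden=6, seed=4)
        a = ssa_bp_train(X, y, cfg, SsaConfig(n_iter=0, seed=0))
        from dataclasses import replace
        b = bp_train(X, y, replace(cfg, max_epochs=1000))
        assert np.array_equal(a.W1, b.W1) and a.b2 == b.b2

    def test_deterministic_under_seeds(self, rng):
        X = rng.normal(size=(50, 2))
        y = X.sum(axis=1) + rng.normal(0, 0.1, 50)
        cfg = BpConfig(n_hidden=5, seed=1)
        scfg = SsaConfig(pop_size=4, n_iter=3, seed=2)
        a = ssa_bp_train(X, y, cfg, scfg)
        b = ssa_bp_train(X, y, cfg, scfg)
        assert np.array_equal(a.W1, b.W1) and np.array_equal(a.w2, b.w2)
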