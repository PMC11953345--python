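"""The nMVAR-ANN estimator: fitting, lC/NC extraction, surrogates."""

import warnings

import numpy as np
import pytest
from scipy.stats import spearmanr

from thetadircomm.ncreann import (NmvarModel, build_design,
                                  concatenate_trials, fit_nmvar_ann,
                                  linear_connectivity, network_average,
                                  nonlinear_connectivity,
                                  normalize_connectivity, phase_randomize,
                                  select_model_order, surrogate_test,
                                  ConnectivityMatrices)
from thetadircomm.synthetic import (NmvarGroundTruth, NonlinearTerm,
                                    simulate_nmvar)
from conftest import random_stationary_var


def toy_model(M=2, p=2, H=3, seed=0):
    rng = np.random.default_rng(seed)
    return NmvarModel(M, p, np.zeros(M), np.ones(M),
                      rng.normal(size=(M, M * p)), rng.normal(size=M),
                      rng.normal(size=(H, M * p)), rng.normal(size=H),
                      rng.normal(size=(M, H)))


class TestModelStructure:
    def test_decomposition_identity(self):
        model = toy_model()
        rng = np.random.default_rng(1)
        Z = rng.normal(size=(50, 4))
        total = model.predict(Z)
        parts = model.linear_part(Z) + model.nonlinear_part(Z) + model.b
        assert np.allclose(total, parts, atol=1e-12)

    def test_concatenation_contract(self):
        # design built on a concatenation with boundaries == pooled
        # within-trial windows
        rng = np.random.default_rng(2)
        trials = rng.normal(size=(3, 2, 30))
        series, bounds = concatenate_trials(trials, window=None)
        Z, Y = build_design(series, 2, boundaries=bounds)
        Zs, Ys = [], []
        for tr in trials:
            z, y = build_design(tr, 2)
            Zs.append(z)
            Ys.append(y)
        assert np.array_equal(Z, np.concatenate(Zs))
        assert np.array_equal(Y, np.concatenate(Ys))

    def test_lagged_column_order(self):
        x = np.arange(12, dtype=float).reshape(2, 6)
        Z, Y = build_design(x, 2)
        # x_p = [x1(n-1), x2(n-1), x1(n-2), x2(n-2)]
        assert np.array_equal(Z[0], [x[0, 1], x[1, 1], x[0, 0], x[1, 0]])
        assert np.array_equal(Y[0], x[:, 2])


class TestFit:
    def test_linear_data_matches_least_squares_oracle(self, var21_truth):
        x = simulate_nmvar(var21_truth, 12000, seed=4)
        model = fit_nmvar_ann(x, 1, seed=0)
        xs = model.standardize(x)
        Z, Y = build_design(xs, 1)
        n_val = len(Z) - model.meta["n_train"]
        Zt, Yt = Z[:-n_val], Y[:-n_val]
        Zv, Yv = Z[-n_val:], Y[-n_val:]
        W = np.linalg.lstsq(Zt, Yt, rcond=None)[0]
        mse_lin = np.mean((Zv @ W - Yv) ** 2)
        assert model.meta["val_loss"] <= 1.10 * mse_lin

    def test_quadratic_coupling_beats_linear_oracle(self, quad_truth):
        x = simulate_nmvar(quad_truth, 20000, seed=5)
        model = fit_nmvar_ann(x, 2, seed=0)
        xs = model.standardize(x)
        Z, Y = build_design(xs, 2)
        n_val = len(Z) - model.meta["n_train"]
        Zt, Yt = Z[:-n_val], Y[:-n_val]
        Zv, Yv = Z[-n_val:], Y[-n_val:]
        W = np.linalg.lstsq(Zt, Yt, rcond=None)[0]
        mse_lin = np.mean((Zv @ W - Yv) ** 2)
        assert model.meta["val_loss"] <= 0.90 * mse_lin

    def test_seed_determinism(self, var21_truth):
        x = simulate_nmvar(var21_truth, 3000, seed=6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m1 = fit_nmvar_ann(x, 1, seed=3)
            m2 = fit_nmvar_ann(x, 1, seed=3)
        for attr in ("W_lin", "b", "U", "c", "V"):
            assert np.array_equal(getattr(m1, attr), getattr(m2, attr))

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError, match="order"):
            fit_nmvar_ann(np.zeros((2, 100)), 0)


class TestConnectivityExtraction:
    def test_lc_arithmetic_by_definition(self):
        model = toy_model(M=2, p=2)
        model.W_lin[:] = 0.0
        # weights for 1 -> 2 (source index 0, target index 1) at both lags
        model.W_lin[1, 0] = 0.5    # lag 1, source 0
        model.W_lin[1, 2] = -0.25  # lag 2, source 0
        lc = linear_connectivity(model)
        expected = np.zeros((2, 2))
        expected[0, 1] = 0.75
        assert np.allclose(lc, expected)

    def test_nc_zero_when_output_weights_zero(self, var21_truth):
        model = toy_model()
        model.V[:] = 0.0
        x = simulate_nmvar(var21_truth, 2000, seed=7)
        assert np.allclose(nonlinear_connectivity(model, x), 0.0)

    def test_lc_recovers_true_edge(self):
        for seed in range(3):
            truth = random_stationary_var(M=3, p=2, seed=seed, n_cross=2)
            x = simulate_nmvar(truth, 20000, seed=seed)
            model = fit_nmvar_ann(x, 2, seed=seed)
            lc = linear_connectivity(model)
            true = truth.true_linear_strength
            off = ~np.eye(3, dtype=bool)
            present = true[off] > 0.1
            if present.any() and (~present).any():
                assert lc[off][present].min() > lc[off][~present].max()


class TestPhaseRandomize:
    def test_periodogram_preserved(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(3, 1024)) + 1.5
        s = phase_randomize(x, seed=1)
        for ch in range(3):
            p0 = np.abs(np.fft.rfft(x[ch])) ** 2
            p1 = np.abs(np.fft.rfft(s[ch])) ** 2
            assert np.allclose(p1, p0, rtol=1e-8, atol=1e-8 * p0.max())
        assert np.allclose(s.mean(axis=1), x.mean(axis=1), atol=1e-10)

    def test_cross_correlation_destroyed(self):
        rng = np.random.default_rng(9)
        base = rng.normal(size=4096)
        x = np.stack([base, 0.9 * base + np.sqrt(1 - 0.81)
                      * rng.normal(size=4096)])
        assert np.corrcoef(x)[0, 1] > 0.85
        for seed in range(10):
            s = phase_randomize(x, seed=seed)
            assert abs(np.corrcoef(s)[0, 1]) < 0.2


class TestModelOrderSelection:
    def test_white_noise_selects_order_one(self):
        truth = NmvarGroundTruth(2, 1, np.zeros((1, 2, 2)))
        hits = 0
        for seed in range(10):
            x = simulate_nmvar(truth, 4000, seed=seed)
            hits += int(select_model_order(x, p_max=5)["bic"] == 1)
        assert hits >= 9

    def test_strong_var2_selects_order_two(self):
        A = np.zeros((2, 2, 2))
        A[0] = [[0.4, 0.3], [0.0, 0.3]]
        A[1] = [[-0.35, 0.0], [0.3, -0.3]]
        truth = NmvarGroundTruth(2, 2, A)
        hits = 0
        for seed in range(10):
            x = simulate_nmvar(truth, 10000, seed=seed)
            hits += int(select_model_order(x, p_max=5)["bic"] == 2)
        assert hits >= 9

    def test_pmax_validation(self):
        with pytest.raises(ValueError):
            select_model_order(np.random.default_rng(0).normal(size=(2, 100)),
                               p_max=30)


class TestSurrogateTest:
    def test_zero_surrogates_masks_all_with_warning(self, var21_truth):
        x = simulate_nmvar(var21_truth, 3000, seed=10)
        with pytest.warns(UserWarning, match="skipped"):
            with warnings.catch_warnings():
                warnings.simplefilter("always")
                cm, ens = surrogate_test(x, 1, n_surrogates=0, seed=0)
        assert cm.lc_mask.all() and cm.nc_mask.all()
        assert ens.n_surrogates == 0

    def test_planted_linear_edge_directional(self, var21_truth):
        hits = 0
        for seed in range(3):
            x = simulate_nmvar(var21_truth, 8000, seed=20 + seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cm, _ = surrogate_test(x, 1, n_surrogates=20, seed=seed)
            hits += int(cm.lc_mask[0, 1] and not cm.lc_mask[1, 0])
        assert hits >= 2


class TestNormalizeAndAverage:
    def cm(self, lc, nc, cond=""):
        return ConnectivityMatrices(np.asarray(lc, float),
                                    np.asarray(nc, float), condition=cond)

    def test_division_by_joint_max(self):
        a = self.cm([[4.0, 2.0], [1.0, 0.5]], [[1.0, 0.2], [0.1, 0.3]])
        b = self.cm([[2.0, 1.0], [0.5, 0.25]], [[0.5, 0.1], [0.05, 2.0]])
        na, nb = normalize_connectivity(a, b)
        assert na.lc.max() == 1.0
        assert nb.lc.max() == pytest.approx(0.5)
        assert nb.nc.max() == 1.0
        # independence of measures: scaling lC leaves NC unchanged
        a2 = self.cm(np.asarray(a.lc) * 10, a.nc)
        na2, _ = normalize_connectivity(a2, b)
        assert np.allclose(na2.nc, na.nc)
        for m in (na, nb):
            assert np.all((m.lc >= 0) & (m.lc <= 1))
            assert np.all((m.nc >= 0) & (m.nc <= 1))

    def test_all_zero_measure_rejected(self):
        a = self.cm(np.zeros((2, 2)), np.ones((2, 2)))
        with pytest.raises(ValueError, match="normalisation undefined"):
            normalize_connectivity(a, a)

    def test_network_average_examples(self):
        m = np.array([[9.0, 2.0], [4.0, 9.0]])
        assert network_average(m) == pytest.approx(3.0)
        assert network_average(m, include_self=True) == pytest.approx(6.0)
        assert network_average(np.eye(3)) == 0.0
        with pytest.raises(ValueError):
            network_average(np.array([[1.0]]))
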