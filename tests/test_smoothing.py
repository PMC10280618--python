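"""Normalisation and L1/L2/Linf cubic fits against independent oracles.

The L1 oracle exploits that a least-absolute-residual polynomial with 4
coefficients can be chosen to interpolate 4 data points: enumerating all
4-subsets and taking the best interpolant is exact for small N.  The
Linf oracle uses the alternation characterisation: the minimax cubic on a
finite point set equioscillates on some 5-point reference; enumerating
5-subsets with alternating-sign solves yields the optimum.
"""

import itertools
import warnings

import numpy as np
import pytest

from glucoppg import (
    design_matrix,
    fit_poly,
    fit_poly_l1,
    fit_poly_l2,
    fit_poly_linf,
    smooth_features,
    smooth_reference,
    unit_energy_normalize,
)
from glucoppg.smoothing import objective


def l1_oracle(x, y):
    """Exact J1 optimum by enumerating 4-point interpolating cubics."""
    best = np.inf
    for idx in itertools.combinations(range(len(x)), 4):
        Xs = design_matrix(x[list(idx)])
        try:
            a = np.linalg.solve(Xs, y[list(idx)])
        except np.linalg.LinAlgError:
            continue
        r = design_matrix(x) @ a - y
        best = min(best, np.sum(np.abs(r)))
    return best


def linf_oracle(x, y):
    """Exact Jinf optimum via 5-point alternation references."""
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    best = np.inf
    for idx in itertools.combinations(range(len(xs)), 5):
        sub_x, sub_y = xs[list(idx)], ys[list(idx)]
        signs = np.array([(-1) ** i for i in range(5)], dtype=float)
        # solve [X | -signs] [a; eps] = y on the reference
        A = np.column_stack([design_matrix(sub_x), -signs])
        try:
            sol = np.linalg.solve(A, sub_y)
        except np.linalg.LinAlgError:
            continue
        a, eps = sol[:4], abs(sol[4])
        resid = np.max(np.abs(design_matrix(xs) @ a - ys))
        if resid <= eps + 1e-9 * (1 + eps):  # feasible reference
            best = min(best, resid)
    return best


def random_instance(rng, n):
    x = np.sort(rng.uniform(-2.0, 2.0, size=n))
    y = rng.normal(size=n)
    return x, y


class TestNormalize:
    def test_three_four_five(self):
        nc = unit_energy_normalize([3.0, 4.0])
        assert nc.gain == pytest.approx(0.2)
        assert np.allclose(nc.values, [0.6, 0.8])

    def test_unit_vector_unchanged(self):
        v = np.array([1.0, 0.0, 0.0])
        nc = unit_energy_normalize(v)
        assert nc.gain == pytest.approx(1.0)
        assert np.allclose(nc.values, v)

    def test_unit_energy_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            nc = unit_energy_normalize(rng.normal(size=17))
            assert np.sum(nc.values**2) == pytest.approx(1.0, abs=1e-10)

    def test_zero_column_warns(self):
        with pytest.warns(UserWarning):
            nc = unit_energy_normalize(np.zeros(5))
        assert nc.gain == 1.0


class TestDesignMatrix:
    @pytest.mark.parametrize("x,row", [([0.0], [1, 0, 0, 0]), ([2.0], [1, 2, 4, 8])])
    def test_rows(self, x, row):
        assert np.allclose(design_matrix(x), [row])

    def test_shape(self):
        assert design_matrix(np.arange(7.0)).shape == (7, 4)


class TestL2:
    def test_exact_cubic_recovered(self):
        x = np.array([0.0, 1, 2, 3, 4])
        fit = fit_poly_l2(x, 1 + x**2)
        assert np.allclose(fit.a, [1, 0, 1, 0], atol=1e-9)
        assert fit.objective == pytest.approx(0.0, abs=1e-18)

    def test_constant_target(self):
        fit = fit_poly_l2(np.array([0.0, 1, 2, 3, 4]), np.full(5, 3.7))
        assert np.allclose(fit.a, [3.7, 0, 0, 0], atol=1e-9)

    def test_residual_orthogonality_vs_normal_equations(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            x, y = random_instance(rng, 9)
            fit = fit_poly_l2(x, y)
            X = design_matrix(x)
            assert np.max(np.abs(X.T @ (X @ fit.a - y))) <= 1e-6 * np.linalg.norm(y)
            a_oracle = np.linalg.solve(X.T @ X, X.T @ y)
            assert np.allclose(fit.fitted, X @ a_oracle, atol=1e-7)


class TestLPFits:
    @pytest.mark.parametrize("fitter", [fit_poly_l1, fit_poly_linf])
    def test_exact_cubic_objective_zero(self, fitter):
        x = np.linspace(-1, 1, 8)
        y = 0.3 - 0.5 * x + 0.2 * x**3
        assert fitter(x, y).objective == pytest.approx(0.0, abs=1e-8)

    def test_l1_matches_interpolation_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x, y = random_instance(rng, 9)
            fit = fit_poly_l1(x, y)
            assert fit.objective == pytest.approx(l1_oracle(x, y), abs=1e-6)

    def test_linf_matches_alternation_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x, y = random_instance(rng, 9)
            fit = fit_poly_linf(x, y)
            assert fit.objective == pytest.approx(linf_oracle(x, y), abs=1e-6)
            # achieved max residual equals the reported optimum
            r = design_matrix(x) @ fit.a - y
            assert np.max(np.abs(r)) == pytest.approx(fit.objective, abs=1e-6)

    def test_outlier_instance_matches_oracle(self):
        x = np.array([0.0, 1, 2, 3, 4])
        y = np.array([0.0, 1, 2, 3, 100])
        fit = fit_poly_l1(x, y)
        assert fit.objective == pytest.approx(l1_oracle(x, y), abs=1e-6)

    def test_objective_orderings(self):
        rng = np.random.default_rng(4)
        for _ in range(15):
            x, y = random_instance(rng, 11)
            f1, f2, fi = fit_poly_l1(x, y), fit_poly_l2(x, y), fit_poly_linf(x, y)
            for other in (f2, fi):
                assert f1.objective <= objective("l1", other.fitted - y) + 1e-6
                assert fi.objective <= objective("linf", other.fitted - y) + 1e-6
            for other in (f1, fi):
                assert f2.objective <= objective("l2", other.fitted - y) + 1e-6

    def test_criteria_agree_on_exact_cubic(self):
        x = np.linspace(0, 3, 10)
        y = 2 - x + 0.5 * x**2 - 0.1 * x**3
        a1 = fit_poly_l1(x, y).a
        a2 = fit_poly_l2(x, y).a
        ai = fit_poly_linf(x, y).a
        assert np.allclose(a1, a2, atol=1e-6)
        assert np.allclose(ai, a2, atol=1e-6)

    def test_degenerate_abscissa_constant_fit(self):
        x = np.full(6, 2.0)
        y = np.array([1.0, 2, 3, 4, 5, 10.0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert fit_poly_l2(x, y).fitted[0] == pytest.approx(np.mean(y))
            assert fit_poly_l1(x, y).fitted[0] == pytest.approx(np.median(y))
            assert fit_poly_linf(x, y).fitted[0] == pytest.approx(5.5)

    def test_unknown_criterion_rejected(self):
        with pytest.raises(ValueError):
            fit_poly(np.arange(5.0), np.arange(5.0), "l3")


class TestSmoothing:
    def test_single_cubic_feature_recovers_glucose(self):
        rng = np.random.default_rng(5)
        feat = np.sort(rng.uniform(-1, 1, size=12))
        glucose = 6 + 2 * feat + 0.5 * feat**3
        out = smooth_reference(feat[:, None], glucose, "l2")
        assert np.allclose(out, glucose, atol=1e-8)

    def test_duplicate_columns_equal_single_column(self):
        rng = np.random.default_rng(6)
        feat = rng.uniform(-1, 1, size=15)
        glucose = rng.uniform(4, 10, size=15)
        single = smooth_reference(feat[:, None], glucose, "l2")
        double = smooth_reference(np.stack([feat, feat], axis=1), glucose, "l2")
        assert np.allclose(single, double, atol=1e-10)

    def test_feature_cubic_in_glucose_unchanged(self):
        rng = np.random.default_rng(7)
        glucose = np.sort(rng.uniform(4, 10, size=12))
        col = 0.1 + 0.02 * glucose - 0.001 * glucose**3
        out = smooth_features(col[:, None], glucose, "l1")
        assert np.allclose(out[:, 0], col, atol=1e-7)

    def test_constant_feature_column_unchanged(self):
        glucose = np.linspace(4, 10, 10)
        col = np.full(10, 0.3)
        out = smooth_features(col[:, None], glucose, "l2")
        assert np.allclose(out[:, 0], 0.3, atol=1e-10)

    @pytest.mark.parametrize("criterion", ["l1", "l2", "linf"])
    def test_permutation_equivariance(self, criterion):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(14, 3))
        g = rng.uniform(4, 10, size=14)
        perm = rng.permutation(14)
        for fn in (smooth_features, smooth_reference):
            base = fn(X, g, criterion)
            permuted = fn(X[perm], g[perm], criterion)
            assert np.allclose(np.asarray(permuted), np.asarray(base)[perm], atol=1e-8)

    @pytest.mark.parametrize("criterion", ["l1", "l2", "linf"])
    def test_noise_reduction_under_cubic_model(self, criterion):
        """Smoothed columns are closer (MSE) to the planted noiseless
        cubic than the raw noisy columns, in most seeded trials."""
        wins = 0
        trials = 20
        for seed in range(trials):
            rng = np.random.default_rng(seed)
            g = np.sort(rng.uniform(4, 10, size=30))
            u = (g - 7) / 3
            truth = 0.5 + 0.3 * u - 0.2 * u**3
            noisy = truth + rng.normal(0, 0.1, size=30)
            sm = smooth_features(noisy[:, None], g, criterion)[:, 0]
            wins += np.mean((sm - truth) ** 2) < np.mean((noisy - truth) ** 2)
        assert wins >= int(0.9 * trials)
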