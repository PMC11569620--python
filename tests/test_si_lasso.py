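"""Lasso correctness (KKT, limits, objective optimality), penalty selection,
noise-scale estimation, and the truncated-Gaussian kernel of selective
inference."""

import numpy as np
import pytest
from scipy import integrate, stats

from peridep.si_lasso import (
    estimate_sigma,
    fit_lasso,
    kkt_violation,
    lambda_grid,
    lambda_max,
    polyhedral_inference,
    select_lambda,
    truncated_gaussian_sf,
)


def _instance(rng, n=60, p=8, k=2, snr=2.0):
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    beta[:k] = snr * rng.choice([-1.0, 1.0], k)
    y = X @ beta + rng.normal(size=n)
    return X, y


class TestFitLasso:
    def test_lambda_max_gives_all_zero_solution(self, rng):
        X, y = _instance(rng)
        fit = fit_lasso(X, y, lambda_max(X, y) * (1 + 1e-10))
        assert fit.active_set.size == 0
        assert fit.intercept == pytest.approx(y.mean())

    def test_just_below_lambda_max_is_nonzero(self, rng):
        X, y = _instance(rng)
        fit = fit_lasso(X, y, lambda_max(X, y) * 0.99)
        assert fit.active_set.size >= 1

    def test_zero_penalty_recovers_ols(self, rng):
        X, y = _instance(rng, n=40, p=5)
        fit = fit_lasso(X, y, 0.0)
        Z = np.column_stack([np.ones(40), X])
        ols = np.linalg.lstsq(Z, y, rcond=None)[0]
        np.testing.assert_allclose(fit.coef, ols[1:], atol=1e-8)
        assert fit.intercept == pytest.approx(ols[0], abs=1e-8)

    def test_kkt_certificate_on_100_random_instances(self):
        rng = np.random.default_rng(55)
        for i in range(100):
            n = int(rng.integers(20, 80))
            p = int(rng.integers(2, 15))
            X, y = _instance(rng, n=n, p=p, k=min(2, p))
            lam = float(rng.uniform(0.01, 1.0)) * lambda_max(X, y)
            fit = fit_lasso(X, y, lam)
            assert fit.converged, f"instance {i}"
            assert fit.kkt_residual < 1e-8, f"instance {i}"

    def test_kkt_violation_detects_a_wrong_solution(self, rng):
        X, y = _instance(rng, n=40, p=4)
        Xs = (X - X.mean(0)) / X.std(0)
        wrong = np.full(4, 2.0)
        assert kkt_violation(Xs, y - y.mean(), wrong, 0.1) > 0.1

    def test_objective_matches_zooming_grid_oracle(self):
        """p=3 instance: the coordinate-descent optimum matches a brute-force
        grid search over the (standardized-coordinates) objective."""
        rng = np.random.default_rng(77)
        X, y = _instance(rng, n=30, p=3, k=1)
        lam = 0.3 * lambda_max(X, y)
        fit = fit_lasso(X, y, lam)
        Xs = (X - X.mean(0)) / X.std(0)
        yc = y - y.mean()
        n = len(y)

        def objective(B):  # B: (m, 3)
            resid = yc[None, :] - B @ Xs.T
            return (0.5 / n) * (resid**2).sum(axis=1) + lam * np.abs(B).sum(axis=1)

        center = np.zeros(3)
        half = 2.0 * np.max(np.abs(np.linalg.lstsq(Xs, yc, rcond=None)[0]))
        for _ in range(10):
            axes = [np.linspace(c - half, c + half, 21) for c in center]
            G = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
            vals = objective(G)
            center = G[vals.argmin()]
            half = half * 2 / 20 * 2  # keep two grid steps around the argmin
        oracle = objective(center[None, :])[0]
        ours = objective(fit.coef_std[None, :])[0]
        assert ours <= oracle + 1e-6

    def test_converged_false_when_iterations_exhausted(self, rng):
        X, y = _instance(rng, n=30, p=10)
        fit = fit_lasso(X, y, 1e-6, max_iter=2, warn=False)
        assert not fit.converged

    def test_numba_and_numpy_paths_agree(self, rng):
        X, y = _instance(rng)
        lam = 0.2 * lambda_max(X, y)
        f1 = fit_lasso(X, y, lam, use_numba=True)
        f2 = fit_lasso(X, y, lam, use_numba=False)
        np.testing.assert_allclose(f1.coef, f2.coef, atol=1e-12)


class TestSelectLambda:
    def test_single_value_grid_returns_it(self, rng):
        X, y = _instance(rng)
        lam, _ = select_lambda(X[:40], y[:40], X[40:], y[40:],
                               grid=np.array([0.123]))
        assert lam == 0.123

    def test_empty_validation_rejected(self, rng):
        X, y = _instance(rng)
        with pytest.raises(ValueError):
            select_lambda(X, y, X[:0], y[:0])

    def test_pure_noise_prefers_sparse_penalties(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            X = rng.normal(size=(100, 10))
            y = rng.normal(size=100)
            Xv = rng.normal(size=(150, 10))
            yv = rng.normal(size=150)
            grid = lambda_grid(X, y)
            lam, _ = select_lambda(X, y, Xv, yv, grid)
            hits += lam >= np.sort(grid)[-5]  # top decile of 50
        assert hits >= 16

    def test_strong_predictor_always_enters(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(2000 + seed)
            X = rng.normal(size=(500, 8))
            y = 3.0 * X[:, 0] + rng.normal(size=500)
            _, fit = select_lambda(X[:350], y[:350], X[350:], y[350:])
            hits += 0 in fit.active_set
        assert hits >= 19


class TestEstimateSigma:
    def test_exact_fit_flags_zero(self, rng):
        X = rng.normal(size=(30, 2))
        y = X @ np.array([1.0, -2.0])
        fit = fit_lasso(X, y, 0.01 * lambda_max(X, y))
        assert estimate_sigma(X, y, fit) == pytest.approx(0.0, abs=1e-10)

    def test_empty_active_set_falls_back_to_sample_sd(self, rng):
        X, y = _instance(rng)
        fit = fit_lasso(X, y, lambda_max(X, y) * 2)
        assert estimate_sigma(X, y, fit) == pytest.approx(np.std(y, ddof=1))

    def test_recovers_known_sigma_within_10_percent(self):
        ests = []
        for seed in range(20):
            rng = np.random.default_rng(3000 + seed)
            X = rng.normal(size=(500, 6))
            y = 2.0 * X[:, 0] + rng.normal(0, 2.0, 500)
            fit = fit_lasso(X, y, 0.3 * lambda_max(X, y))
            ests.append(estimate_sigma(X, y, fit))
        assert abs(np.mean(ests) - 2.0) <= 0.2

    def test_saturated_active_set_is_an_error(self, rng):
        X = rng.normal(size=(4, 6))
        y = rng.normal(size=4)
        fit = fit_lasso(X, y, 1e-4 * lambda_max(X, y), warn=False)
        if fit.active_set.size + 1 >= 4:
            with pytest.raises(ValueError):
                estimate_sigma(X, y, fit)


class TestTruncatedGaussianSF:
    def test_untruncated_limit_is_the_gaussian_sf(self):
        for x in (-2.0, 0.0, 1.7):
            assert truncated_gaussian_sf(x, 0, 1, -np.inf, np.inf) == \
                pytest.approx(stats.norm.sf(x), rel=1e-12)

    def test_boundaries_clamp_with_warning(self):
        with pytest.warns(UserWarning):
            assert truncated_gaussian_sf(0.5, 0, 1, 1, 2) == 1.0
        with pytest.warns(UserWarning):
            assert truncated_gaussian_sf(2.5, 0, 1, 1, 2) == 0.0

    def test_matches_quadrature_to_1e8(self):
        rng = np.random.default_rng(8)
        cases = []
        for _ in range(40):
            a = rng.uniform(-8, 7)
            b = a + rng.uniform(0.2, 4)
            x = rng.uniform(a + 1e-3, b - 1e-3)
            mu = rng.uniform(-2, 2)
            sigma = rng.uniform(0.5, 2)
            cases.append((x, mu, sigma, a, b))
        for x, mu, sigma, a, b in cases:
            num, _ = integrate.quad(stats.norm(mu, sigma).pdf, x, b,
                                    epsabs=1e-14, epsrel=1e-12)
            den, _ = integrate.quad(stats.norm(mu, sigma).pdf, a, b,
                                    epsabs=1e-14, epsrel=1e-12)
            expected = num / den
            got = truncated_gaussian_sf(x, mu, sigma, a, b)
            assert got == pytest.approx(expected, rel=1e-8, abs=1e-12)

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            truncated_gaussian_sf(0, 0, 1, 2, 1)
        with pytest.raises(ValueError):
            truncated_gaussian_sf(0, 0, -1, 0, 1)


class TestPolyhedralInference:
    def test_single_column_matches_closed_form(self):
        """For one standardized column the selection event is just
        |x'y|/n > lambda, so the selective p-value has a closed form: the
        truncated-Gaussian tail beyond the observed statistic with the
        truncation threshold at lambda."""
        rng = np.random.default_rng(21)
        n = 50
        x = rng.normal(size=(n, 1))
        sigma = 1.0
        lam = 0.15
        for _ in range(50):
            y = rng.normal(size=n)
            fit = fit_lasso(x, y, lam)
            if fit.active_set.size == 0:
                continue
            summ = polyhedral_inference(x, y, fit, sigma)
            xs = (x[:, 0] - x[:, 0].mean()) / x[:, 0].std()
            T = xs @ (y - y.mean()) / (xs @ xs)
            sd = sigma / np.sqrt(xs @ xs)
            if fit.signs[0] > 0:
                expected = truncated_gaussian_sf(T, 0, sd, lam, np.inf)
            else:
                expected = 1 - truncated_gaussian_sf(T, 0, sd, -np.inf, -lam)
            assert summ.p_value[0] == pytest.approx(expected, abs=1e-6)
            break
        else:  # pragma: no cover
            pytest.fail("selection never occurred")

    def test_truncation_brackets_the_statistic_and_ci_contains_estimate(self, rng):
        X, y = _instance(rng, n=80, p=6, k=2)
        fit = fit_lasso(X, y, 0.3 * lambda_max(X, y))
        summ = polyhedral_inference(X, y, fit, 1.0)
        assert (summ.v_minus < summ.observed).all()
        assert (summ.observed < summ.v_plus).all()
        assert (summ.ci_lower <= summ.estimate).all()
        assert (summ.estimate <= summ.ci_upper).all()
        assert ((0 <= summ.p_value) & (summ.p_value <= 1)).all()

    def test_vanishing_truncation_recovers_unadjusted_interval(self):
        """With overwhelming signal the truncation constraint is far from the
        observed statistic and the selective CI approaches the OLS CI."""
        rng = np.random.default_rng(31)
        n = 400
        X = rng.normal(size=(n, 2))
        sigma = 1.0
        y = 10.0 * X[:, 0] - 8.0 * X[:, 1] + rng.normal(size=n)
        fit = fit_lasso(X, y, 0.05 * lambda_max(X, y))
        summ = polyhedral_inference(X, y, fit, sigma)
        Xs = (X - X.mean(0)) / X.std(0)
        M = np.linalg.inv(Xs.T @ Xs)
        for j, idx in enumerate(summ.indices):
            se = sigma * np.sqrt(M[j, j])
            lo = summ.observed[j] - 1.959963984540054 * se
            hi = summ.observed[j] + 1.959963984540054 * se
            width = hi - lo
            assert abs(summ.ci_lower[j] - lo) < 0.05 * width
            assert abs(summ.ci_upper[j] - hi) < 0.05 * width

    def test_empty_active_set_gives_empty_summary(self, rng):
        X, y = _instance(rng)
        fit = fit_lasso(X, y, lambda_max(X, y) * 2)
        summ = polyhedral_inference(X, y, fit, 1.0)
        assert len(summ) == 0

    def test_active_set_size_monotone_along_path(self):
        rng = np.random.default_rng(41)
        X = rng.normal(size=(200, 10))
        beta = np.concatenate([np.array([3.0, -2.0, 1.0]), np.zeros(7)])
        y = X @ beta + rng.normal(size=200)
        sizes = []
        warm = None
        for lam in lambda_grid(X, y, 30):
            fit = fit_lasso(X, y, lam, warm_start=warm)
            warm = fit.coef_std
            sizes.append(fit.active_set.size)
        # grid is descending in lambda, so sizes should be non-decreasing
        assert all(b >= a for a, b in zip(sizes, sizes[1:]))
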