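"""Coordinate-descent LASSO solver against analytic and brute-force oracles."""

import itertools

import numpy as np
import pytest

from snplasso.lasso import (
    LassoConfig,
    fit_path,
    fit_single,
    kkt_violations,
    lambda_grid,
    lambda_max,
    objective,
    predict,
    soft_threshold,
)


def lasso_objective(X, y, b0, b, lam):
    n = X.shape[0]
    r = y - b0 - X @ b
    return 0.5 * float(r @ r) / n + lam * float(np.sum(np.abs(b)))


def sign_pattern_oracle(X, y, lam):
    """Global minimum of (1/(2n))RSS + lam*||b||_1 by sign-pattern enumeration.

    For each of the 3^p sign patterns, solves the stationarity system for
    the nonzero block, keeps solutions whose signs and subgradients are
    consistent, and returns the smallest objective found.  Penalty on the
    raw coefficient scale (compare with standardize=False fits).
    """
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    best = np.inf
    for signs in itertools.product((-1, 0, 1), repeat=p):
        s = np.array(signs, dtype=float)
        act = np.nonzero(s)[0]
        b = np.zeros(p)
        if act.size:
            A = Xc[:, act]
            try:
                b_act = np.linalg.solve(
                    A.T @ A / n, A.T @ yc / n - lam * s[act]
                )
            except np.linalg.LinAlgError:
                continue
            if np.any(np.sign(b_act) != s[act]):
                continue
            b[act] = b_act
        grad = Xc.T @ (yc - Xc @ b) / n
        inact = np.setdiff1d(np.arange(p), act)
        if np.any(np.abs(grad[inact]) > lam + 1e-10):
            continue
        b0 = y.mean() - float(b @ X.mean(axis=0))
        best = min(best, lasso_objective(X, y, b0, b, lam))
    return best


def random_instance(seed, n=30, p=6, corr=0.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    if corr:
        X += corr * rng.normal(size=(n, 1))
    beta = rng.normal(size=p) * rng.binomial(1, 0.5, size=p)
    y = X @ beta + rng.normal(size=n)
    return X, y


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "z,gamma,expected",
        [(3.0, 1.0, 2.0), (-0.5, 1.0, 0.0), (-3.0, 1.0, -2.0), (0.7, 0.0, 0.7)],
    )
    def test_values(self, z, gamma, expected):
        assert soft_threshold(z, gamma) == expected

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(1.0, -0.1)


class TestLambdaMax:
    def test_zero_response(self):
        X = np.random.default_rng(0).normal(size=(20, 4))
        assert lambda_max(X, np.zeros(20)) == 0.0

    def test_single_column_arithmetic(self):
        # standardized column with (1/n) x.y = 0.3 exactly
        n = 10
        x = np.array([1.0, -1.0] * 5)
        y = 0.3 * x  # (1/n) sum x_i y_i = 0.3 since x is +-1
        assert lambda_max(x[:, None], y) == pytest.approx(0.3, abs=1e-12)

    def test_fit_above_lambda_max_is_zero(self):
        X, y = random_instance(3)
        lam0 = lambda_max(X, y)
        path = fit_single(X, y, 1.01 * lam0)
        assert np.all(path.coefs == 0)
        assert path.intercepts[0] == pytest.approx(y.mean())
        assert kkt_violations(path, X, y, 0) == 0


class TestFitPath:
    def test_path_top_is_zero_with_mean_intercept(self):
        X, y = random_instance(5)
        path = fit_path(X, y, LassoConfig(n_lambda=30))
        assert path.n_nonzero[0] == 0
        assert path.intercepts[0] == pytest.approx(y.mean())

    def test_orthonormal_design_closed_form(self):
        """On an exactly orthonormal standardized design the solution is
        coordinate-wise soft-thresholding of the OLS estimate."""
        rng = np.random.default_rng(7)
        n, p = 40, 6
        A = rng.normal(size=(n, p))
        A -= A.mean(axis=0)
        Q, _ = np.linalg.qr(A)
        X = Q * np.sqrt(n)  # columns: mean ~0, (1/n) X^T X = I
        X -= X.mean(axis=0)
        y = rng.normal(size=n) + X @ rng.normal(size=p)
        b_ols = X.T @ (y - y.mean()) / n
        for lam in (0.05, 0.3, 0.8):
            path = fit_single(X, y, lam, LassoConfig(tol=1e-12))
            expected = np.sign(b_ols) * np.maximum(np.abs(b_ols) - lam, 0)
            # report scale differs from unit-variance scale by columns' SD
            sd = X.std(axis=0)
            assert np.allclose(path.coefs[:, 0] * sd, expected, atol=1e-10)

    @pytest.mark.parametrize("corr", [0.0, 1.5])
    def test_sign_pattern_oracle_equivalence(self, corr):
        """Objective value matches exhaustive sign-pattern enumeration."""
        cfg = LassoConfig(standardize=False, tol=1e-12)
        for seed in range(12):
            X, y = random_instance(seed, n=30, p=5, corr=corr)
            lam = 0.25 * lambda_max(X, y, cfg)
            path = fit_single(X, y, lam, cfg)
            ours = lasso_objective(X, y, path.intercepts[0], path.coefs[:, 0], lam)
            assert ours == pytest.approx(sign_pattern_oracle(X, y, lam), abs=1e-8)

    def test_ols_limit_for_small_lambda(self):
        """With p < n the lasso approaches the OLS fit as lambda -> 0."""
        X, y = random_instance(11, n=60, p=8)
        cfg = LassoConfig(n_lambda=60, lambda_min_ratio=1e-6, tol=1e-11)
        path = fit_path(X, y, cfg)
        Xd = np.column_stack([np.ones(60), X])
        b_ols = np.linalg.lstsq(Xd, y, rcond=None)[0][1:]
        err = np.max(np.abs(path.coefs[:, -1] - b_ols))
        assert err < 1e-3 * np.max(np.abs(b_ols))

    def test_l1_norm_monotone_along_path(self):
        X, y = random_instance(13, n=50, p=10)
        path = fit_path(X, y, LassoConfig(n_lambda=40, tol=1e-10))
        # standardized-scale l1 norms are non-increasing in lambda
        norms = np.sum(np.abs(path.coefs * path.x_scale[:, None]), axis=0)
        assert np.all(np.diff(norms) >= -1e-9)

    def test_objective_non_increasing_across_sweeps(self):
        """Driving the solver one sweep at a time, the penalized objective
        never increases."""
        X, y = random_instance(17, n=40, p=12, corr=1.0)
        lam = 0.1 * lambda_max(X, y)
        prev = np.inf
        beta_prev = None
        for sweeps in range(1, 15):
            cfg = LassoConfig(tol=1e-15, max_iter=sweeps)
            path = fit_single(X, y, lam, cfg)
            obj = lasso_objective(X, y, path.intercepts[0], path.coefs[:, 0], lam)
            assert obj <= prev + 1e-12 * (1 + abs(prev))
            prev = obj
        # the solver's own internal check agrees (converged implies obj_ok)
        full = fit_single(X, y, lam, LassoConfig(tol=1e-10))
        assert full.converged[0]

    def test_scale_invariance_of_original_scale_solution(self):
        """Rescaling a predictor column by a positive constant leaves the
        original-scale fit unchanged when standardization is on."""
        X, y = random_instance(19, n=50, p=6)
        cfg = LassoConfig(tol=1e-12)
        lam = 0.2 * lambda_max(X, y, cfg)
        base = fit_single(X, y, lam, cfg)
        X2 = X.copy()
        X2[:, 2] *= 37.5
        scaled = fit_single(X2, y, lam, cfg)
        unscaled = scaled.coefs[:, 0].copy()
        unscaled[2] *= 37.5
        assert np.allclose(unscaled, base.coefs[:, 0], atol=1e-9)

    def test_constant_column_gets_zero_coefficient(self):
        X, y = random_instance(23, n=30, p=4)
        X[:, 1] = 5.0
        path = fit_path(X, y, LassoConfig(n_lambda=10))
        assert np.all(path.coefs[1, :] == 0)

    def test_plain_rss_scaling_equivalence(self):
        """A plain-RSS lambda of 2n*lam gives the half-mean solution at lam."""
        X, y = random_instance(29, n=40, p=5)
        lam = 0.15
        a = fit_single(X, y, lam, LassoConfig(tol=1e-12))
        b = fit_single(X, y, 2 * 40 * lam,
                       LassoConfig(tol=1e-12, rss_scaling="plain"))
        assert np.allclose(a.coefs, b.coefs, atol=1e-10)

    def test_missing_values_rejected(self):
        X, y = random_instance(31)
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_path(X, y)


class TestKKT:
    def test_converged_fits_have_zero_violations(self):
        for seed in range(5):
            X, y = random_instance(seed, n=40, p=10, corr=1.0)
            path = fit_path(X, y, LassoConfig(n_lambda=25, tol=1e-10))
            assert path.converged.all()
            for l in (0, 12, 24):
                assert kkt_violations(path, X, y, l, kkt_tol=1e-6) == 0

    def test_truncated_solver_violates_kkt(self):
        """One sweep on a strongly correlated design must leave violations."""
        rng = np.random.default_rng(42)
        n, p = 60, 15
        base = rng.normal(size=(n, 1))
        X = base + 0.08 * rng.normal(size=(n, p))
        y = X @ rng.normal(size=p) + 0.1 * rng.normal(size=n)
        lam = 0.01 * lambda_max(X, y)
        path = fit_single(X, y, lam, LassoConfig(tol=1e-15, max_iter=1))
        assert not path.converged[0]
        assert kkt_violations(path, X, y, 0, kkt_tol=1e-6) > 0

    def test_agrees_with_independent_reference_solver(self):
        """Coefficients match scikit-learn's Lasso (an independent
        implementation of the same 1/(2n)-scaled objective) to 1e-9."""
        from sklearn.linear_model import Lasso

        rng = np.random.default_rng(77)
        n, p = 70, 12
        X = rng.normal(size=(n, p)) * rng.uniform(0.5, 3, size=p)
        y = X @ (rng.normal(size=p) * rng.binomial(1, 0.5, p)) + rng.normal(size=n)
        for alpha in (0.5, 0.1, 0.02):
            ours = fit_single(X, y, alpha,
                              LassoConfig(standardize=False, tol=1e-12))
            ref = Lasso(alpha=alpha, tol=1e-12, max_iter=200_000).fit(X, y)
            assert np.allclose(ours.coefs[:, 0], ref.coef_, atol=1e-9)
            assert ours.intercepts[0] == pytest.approx(ref.intercept_, abs=1e-9)

    def test_screening_does_not_change_solutions(self):
        X, y = random_instance(101, n=50, p=20, corr=0.8)
        cfg_off = LassoConfig(n_lambda=30, tol=1e-10, screen=False)
        cfg_on = LassoConfig(n_lambda=30, tol=1e-10, screen=True)
        a = fit_path(X, y, cfg_off)
        b = fit_path(X, y, cfg_on)
        assert np.allclose(a.coefs, b.coefs, atol=1e-12)
        assert np.allclose(a.intercepts, b.intercepts, atol=1e-12)


class TestPredict:
    def test_zero_model_predicts_mean(self):
        X, y = random_instance(2)
        path = fit_single(X, y, 2 * lambda_max(X, y))
        assert np.allclose(predict(path, X, 0), y.mean())

    def test_prediction_permutation_equivariance(self):
        X, y = random_instance(4)
        path = fit_path(X, y, LassoConfig(n_lambda=10))
        perm = np.random.default_rng(0).permutation(X.shape[0])
        assert np.allclose(predict(path, X[perm], 5), predict(path, X, 5)[perm])

    def test_column_mismatch_rejected(self):
        X, y = random_instance(6)
        path = fit_path(X, y, LassoConfig(n_lambda=5))
        with pytest.raises(ValueError, match="columns"):
            predict(path, X[:, :3], 0)

    def test_training_prediction_matches_ols_at_tiny_lambda(self):
        X, y = random_instance(8, n=80, p=6)
        cfg = LassoConfig(n_lambda=50, lambda_min_ratio=1e-7, tol=1e-12)
        path = fit_path(X, y, cfg)
        Xd = np.column_stack([np.ones(80), X])
        yhat_ols = Xd @ np.linalg.lstsq(Xd, y, rcond=None)[0]
        assert np.allclose(predict(path, X, path.n_lambda - 1), yhat_ols, atol=1e-4)


def test_lambda_grid_shape_and_endpoints():
    X, y = random_instance(9)
    cfg = LassoConfig(n_lambda=20, lambda_min_ratio=0.01)
    grid = lambda_grid(X, y, cfg)
    assert len(grid) == 20
    assert grid[0] == pytest.approx(lambda_max(X, y, cfg))
    assert grid[-1] == pytest.approx(0.01 * grid[0])
    assert np.all(np.diff(grid) < 0)


def test_objective_helper_matches_reference():
    X, y = random_instance(10)
    path = fit_single(X, y, 0.1)
    ours = objective(X, y, path.intercepts[0], path.coefs[:, 0], 0.1,
                     x_scale=path.x_scale)
    n = X.shape[0]
    r = y - path.intercepts[0] - X @ path.coefs[:, 0]
    ref = 0.5 * float(r @ r) / n + 0.1 * float(
        np.sum(np.abs(path.coefs[:, 0] * path.x_scale)))
    assert ours == pytest.approx(ref, rel=1e-12)
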