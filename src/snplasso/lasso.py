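"""Coordinate-descent LASSO with regularization path, warm starts and KKT checks.

The solver minimizes

    (1/(2n)) * sum_i (y_i - b0 - sum_j b_j x_ij)^2  +  lam * sum_j |b_j|

by cyclic coordinate descent on (internally) standardized predictors, with
the coordinate-wise soft-thresholding update.  The 1/(2n) scaling makes the
penalty commensurable across sample sizes (so cross-validated lambdas can be
compared between folds and data sets); ``rss_scaling="plain"`` exposes the
unscaled-RSS convention, in which a user-facing lambda is 2n times larger.

The path is fit on a descending log-spaced lambda grid from lambda_max (the
smallest penalty with an all-zero solution) with warm starts; each lambda
alternates full sweeps with active-set iteration and ends with a confirming
full sweep.  Optional sequential strong-rule screening restricts sweeps to a
candidate set and is always backstopped by a full KKT scan, so enabling it
cannot change the solution.  The intercept is never penalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit


def soft_threshold(z: float, gamma: float) -> float:
    """S(z, gamma) = sign(z) * max(|z| - gamma, 0)."""
    if gamma < 0:
        raise ValueError("soft-threshold parameter must be >= 0")
    return float(np.sign(z) * max(abs(z) - gamma, 0.0))


@dataclass
class LassoConfig:
    n_lambda: int = 100
    lambda_min_ratio: float | None = None  # default 1e-4 if n > p else 1e-2
    tol: float = 1e-7
    max_iter: int = 100_000
    standardize: bool = True
    rss_scaling: str = "half_mean"  # or "plain" (unscaled RSS)
    screen: bool = False  # strong-rule screening (KKT-backstopped)

    def __post_init__(self) -> None:
        if self.lambda_min_ratio is not None and not 0 < self.lambda_min_ratio < 1:
            raise ValueError("lambda_min_ratio must be in (0, 1)")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.rss_scaling not in ("half_mean", "plain"):
            raise ValueError("rss_scaling must be 'half_mean' or 'plain'")

    def resolved_min_ratio(self, n: int, p: int) -> float:
        if self.lambda_min_ratio is not None:
            return self.lambda_min_ratio
        return 1e-4 if n > p else 1e-2


@dataclass
class LassoPath:
    """Solutions along a descending lambda grid, on the original x scale."""

    lambdas: np.ndarray  # user-convention, descending
    coefs: np.ndarray  # p x n_lambda, original scale
    intercepts: np.ndarray
    n_nonzero: np.ndarray
    converged: np.ndarray  # per-lambda flags; False is surfaced, never silent
    x_mean: np.ndarray
    x_scale: np.ndarray  # divisor used for standardization (1.0 where off)
    y_mean: float
    n_samples: int
    rss_scaling: str = "half_mean"
    sweeps: np.ndarray = field(default=None)

    @property
    def n_lambda(self) -> int:
        return len(self.lambdas)

    def coef_at(self, lambda_index: int) -> tuple[float, np.ndarray]:
        return float(self.intercepts[lambda_index]), self.coefs[:, lambda_index]


@njit(cache=True)
def _cd_solve(X, r, beta, means, inv_s, colvar, allowed, lam, tol, max_sweeps,
              obj_slack):
    """Cyclic coordinate descent at one lambda over the ``allowed`` columns.

    X is the raw (n x p, Fortran-order) design; standardization is applied on
    the fly via ``means``/``inv_s``.  ``colvar`` holds the variance of each
    (internally scaled) column — exactly 1 under standardization.  ``r`` is
    the current residual of the centered problem and ``beta`` the
    standardized-scale coefficients; both are updated in place (warm start).
    Returns (sweeps, converged, obj_ok).
    """
    n = X.shape[0]
    sweeps = 0
    converged = False
    obj_ok = True
    obj_prev = np.inf
    while sweeps < max_sweeps:
        # full sweep over the allowed set
        maxd = 0.0
        for t in range(allowed.size):
            j = allowed[t]
            acc = 0.0
            for i in range(n):
                acc += X[i, j] * r[i]
            g = inv_s[j] * acc / n
            z = g + colvar[j] * beta[j]
            new = np.sign(z) * max(abs(z) - lam, 0.0) / colvar[j]
            d = new - beta[j]
            if d != 0.0:
                beta[j] = new
                c = d * inv_s[j]
                m = means[j]
                for i in range(n):
                    r[i] -= c * (X[i, j] - m)
                if abs(d) > maxd:
                    maxd = abs(d)
        sweeps += 1
        rss = 0.0
        for i in range(n):
            rss += r[i] * r[i]
        pen = 0.0
        for t in range(allowed.size):
            pen += abs(beta[allowed[t]])
        obj = 0.5 * rss / n + lam * pen
        if obj > obj_prev + obj_slack * (1.0 + abs(obj_prev)):
            obj_ok = False
        obj_prev = obj
        if maxd < tol:
            converged = True
            break
        # iterate on the active set until stable, then confirm with full sweep
        n_active = 0
        for t in range(allowed.size):
            if beta[allowed[t]] != 0.0:
                n_active += 1
        active = np.empty(n_active, dtype=np.int64)
        k = 0
        for t in range(allowed.size):
            if beta[allowed[t]] != 0.0:
                active[k] = allowed[t]
                k += 1
        while sweeps < max_sweeps:
            maxd_a = 0.0
            for t in range(active.size):
                j = active[t]
                acc = 0.0
                for i in range(n):
                    acc += X[i, j] * r[i]
                g = inv_s[j] * acc / n
                z = g + colvar[j] * beta[j]
                new = np.sign(z) * max(abs(z) - lam, 0.0) / colvar[j]
                d = new - beta[j]
                if d != 0.0:
                    beta[j] = new
                    c = d * inv_s[j]
                    m = means[j]
                    for i in range(n):
                        r[i] -= c * (X[i, j] - m)
                    if abs(d) > maxd_a:
                        maxd_a = abs(d)
            sweeps += 1
            rss = 0.0
            for i in range(n):
                rss += r[i] * r[i]
            pen = 0.0
            for t in range(allowed.size):
                pen += abs(beta[allowed[t]])
            obj = 0.5 * rss / n + lam * pen
            if obj > obj_prev + obj_slack * (1.0 + abs(obj_prev)):
                obj_ok = False
            obj_prev = obj
            if maxd_a < tol:
                break
    return sweeps, converged, obj_ok


def _standardization(X: np.ndarray, standardize: bool):
    """Column means, standardization divisors (population SD) and inverse.

    Zero-variance columns get inv_s = 0, which freezes their coefficient at
    zero (they can never enter the model).
    """
    means = X.mean(axis=0, dtype=np.float64)
    var = np.var(X, axis=0, dtype=np.float64)
    if standardize:
        scale = np.sqrt(np.maximum(var, 0.0))
    else:
        scale = np.where(var > 0, 1.0, 0.0)
    with np.errstate(divide="ignore"):
        inv_s = np.where(scale > 0, 1.0 / np.where(scale > 0, scale, 1.0), 0.0)
    return means.astype(np.float64), scale.astype(np.float64), inv_s.astype(np.float64)


def _grad_all(X, r, inv_s, n):
    """Full standardized gradient (1/n) x_tilde^T r; centered r sums to zero,
    so the mean term vanishes."""
    return inv_s * (X.T @ np.asarray(r, dtype=X.dtype)).astype(np.float64) / n


def lambda_max(X: np.ndarray, y: np.ndarray, config: LassoConfig | None = None) -> float:
    """Smallest penalty at which the all-zero coefficient vector is optimal.

    max_j |x_tilde_j^T y_c| / n on standardized predictors and centered y
    (half-mean convention; multiplied by 2n under ``rss_scaling="plain"``).
    """
    config = config or LassoConfig()
    X = np.asarray(X)
    y = np.asarray(y, dtype=np.float64)
    n = X.shape[0]
    means, scale, inv_s = _standardization(X, config.standardize)
    if config.standardize and np.all(scale == 0):
        raise ValueError("all columns have zero variance; nothing to standardize")
    y_c = y - y.mean()
    lam = float(np.max(np.abs(_grad_all(X, y_c, inv_s, n)))) if X.shape[1] else 0.0
    if config.rss_scaling == "plain":
        lam *= 2 * n
    return lam


def lambda_grid(X: np.ndarray, y: np.ndarray, config: LassoConfig) -> np.ndarray:
    """Descending log-spaced grid from lambda_max to ratio * lambda_max."""
    lam0 = lambda_max(X, y, config)
    if lam0 == 0:
        return np.zeros(1)
    ratio = config.resolved_min_ratio(*X.shape)
    return lam0 * np.logspace(0, np.log10(ratio), config.n_lambda)


def fit_path(
    X: np.ndarray,
    y: np.ndarray,
    config: LassoConfig | None = None,
    lambdas: np.ndarray | None = None,
) -> LassoPath:
    """Fit the LASSO regularization path by pathwise coordinate descent.

    ``lambdas`` overrides the automatic grid (must be descending); solutions
    are warm-started from the previous grid point.  X must be fully observed
    (mean-impute missing dosages first); constant columns are tolerated and
    kept at coefficient zero.
    """
    config = config or LassoConfig()
    X = np.asarray(X)
    if X.dtype not in (np.float32, np.float64):
        X = X.astype(np.float64)
    X = np.asfortranarray(X)
    y = np.asarray(y, dtype=np.float64)
    n, p = X.shape
    if n < 1:
        raise ValueError("need at least 1 sample")
    if y.shape != (n,):
        raise ValueError("y length does not match X rows")
    if np.isnan(X).any():
        raise ValueError("X contains missing values; impute before fitting")

    means, scale, inv_s = _standardization(X, config.standardize)
    usable = np.where(inv_s > 0)[0]
    # variance of each internally scaled column (exactly 1 when standardizing)
    if config.standardize:
        colvar = np.ones(p)
    else:
        colvar = np.var(X, axis=0, dtype=np.float64)
        colvar[inv_s == 0] = 1.0
    y_mean = float(y.mean())
    y_c = y - y_mean

    if lambdas is None:
        lams_user = lambda_grid(X, y, config)
    else:
        lams_user = np.asarray(lambdas, dtype=np.float64)
        if np.any(np.diff(lams_user) > 0):
            raise ValueError("lambda grid must be descending")
    conv = config.rss_scaling == "plain"
    lams = lams_user / (2 * n) if conv else lams_user

    L = len(lams)
    beta = np.zeros(p)  # standardized scale, warm-started across the grid
    r = y_c.copy()
    coefs = np.empty((p, L))
    intercepts = np.empty(L)
    n_nonzero = np.empty(L, dtype=np.int64)
    converged = np.empty(L, dtype=bool)
    sweeps_used = np.empty(L, dtype=np.int64)

    # float32 designs cannot resolve standardized-coefficient changes below
    # ~1e-6; floor the tolerance there so convergence remains decidable
    tol = max(config.tol, 1e-6) if X.dtype == np.float32 else config.tol
    obj_slack = 1e-6 if X.dtype == np.float32 else 1e-10
    grad = None  # full gradient at previous solution, for strong screening
    for l, lam in enumerate(lams):
        if config.screen:
            # sequential strong rule: |g_j(prev)| >= 2*lam - lam_prev; at the
            # top of the grid start from the empty set (the all-zero solution
            # is optimal at lambda_max; the KKT backstop repairs any other case)
            if grad is None:
                cand = beta != 0
            else:
                thresh = 2 * lam - lams[l - 1]
                cand = (np.abs(grad) >= thresh) | (beta != 0)
            allowed = usable[cand[usable]]
        else:
            allowed = usable
        total_sw = 0
        ok = True
        obj_ok = True
        while True:
            sw, conv_flag, oflag = _cd_solve(
                X, r, beta, means, inv_s, colvar, allowed,
                lam, tol, config.max_iter - total_sw, obj_slack,
            )
            total_sw += sw
            ok = conv_flag
            obj_ok = obj_ok and oflag
            grad = _grad_all(X, r, inv_s, n)
            if not config.screen:
                break
            # KKT backstop over the columns that were screened out
            viol = np.zeros(p, dtype=bool)
            viol[usable] = np.abs(grad[usable]) > lam + tol
            viol[allowed] = False
            if not viol.any() or total_sw >= config.max_iter:
                break
            allowed = np.union1d(allowed, np.where(viol)[0])
        converged[l] = ok and obj_ok
        sweeps_used[l] = total_sw
        b_orig = beta * inv_s
        coefs[:, l] = b_orig
        intercepts[l] = y_mean - float(b_orig @ means)
        n_nonzero[l] = int(np.count_nonzero(beta))

    return LassoPath(
        lambdas=lams_user,
        coefs=coefs,
        intercepts=intercepts,
        n_nonzero=n_nonzero,
        converged=converged,
        x_mean=means,
        x_scale=np.where(scale > 0, scale, 1.0),
        y_mean=y_mean,
        n_samples=n,
        rss_scaling=config.rss_scaling,
        sweeps=sweeps_used,
    )


def fit_single(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    config: LassoConfig | None = None,
) -> LassoPath:
    """Fit at a single penalty (cold start); a one-point :class:`LassoPath`."""
    return fit_path(X, y, config=config, lambdas=np.array([lam]))


def predict(path: LassoPath, X: np.ndarray, lambda_index: int) -> np.ndarray:
    """Predictions b0 + X b at one grid point, original scale."""
    X = np.asarray(X)
    if X.shape[1] != path.coefs.shape[0]:
        raise ValueError(
            f"X has {X.shape[1]} columns, path was fit with {path.coefs.shape[0]}"
        )
    b0, b = path.coef_at(lambda_index)
    nz = np.nonzero(b)[0]
    if nz.size == 0:
        return np.full(X.shape[0], b0)
    return b0 + X[:, nz].astype(np.float64) @ b[nz]


def objective(
    X: np.ndarray,
    y: np.ndarray,
    intercept: float,
    coefs: np.ndarray,
    lam: float,
    rss_scaling: str = "half_mean",
    x_scale: np.ndarray | None = None,
) -> float:
    """Penalized objective value; the penalty applies to standardized-scale
    coefficients (coef * x_scale) when a scale is given."""
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    resid = np.asarray(y, dtype=np.float64) - intercept - X @ coefs
    rss = float(resid @ resid)
    b_std = coefs * (x_scale if x_scale is not None else 1.0)
    pen = float(np.sum(np.abs(b_std)))
    if rss_scaling == "half_mean":
        return 0.5 * rss / n + lam * pen
    return rss + lam * pen


def kkt_violations(
    path: LassoPath,
    X: np.ndarray,
    y: np.ndarray,
    lambda_index: int,
    kkt_tol: float = 1e-6,
) -> int:
    """Count first-order optimality violations at one grid point.

    With standardized predictors and g_j = (1/n) x_tilde_j^T (y - yhat):
    a zero coefficient violates if |g_j| > lam + tol; a nonzero one if
    |g_j - lam * sign| > tol.  Zero-variance columns are exempt.
    """
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    lam = path.lambdas[lambda_index]
    if path.rss_scaling == "plain":
        lam = lam / (2 * path.n_samples)
    b0, b = path.coef_at(lambda_index)
    resid = np.asarray(y, dtype=np.float64) - b0 - X @ b
    x_tilde_t_r = (X.T @ resid) - path.x_mean * resid.sum()
    variable = np.sqrt(np.maximum(X.var(axis=0), 0)) > 0
    g = np.where(variable, x_tilde_t_r / path.x_scale / n, 0.0)
    b_std = b * path.x_scale
    zero = b_std == 0
    v_zero = zero & variable & (np.abs(g) > lam + kkt_tol)
    v_nonzero = ~zero & (np.abs(g - lam * np.sign(b_std)) > kkt_tol)
    return int(np.sum(v_zero) + np.sum(v_nonzero))


def export_path_tsv(path: LassoPath, snp_ids, out_summary, out_coefs) -> None:
    """Write (lambda, n_nonzero, intercept) and sparse coefficient triples."""
    import pandas as pd

    pd.DataFrame(
        {
            "lambda": path.lambdas,
            "n_nonzero": path.n_nonzero,
            "intercept": path.intercepts,
            "converged": path.converged,
        }
    ).to_csv(out_summary, sep="\t", index=False)
    rows = []
    snp_ids = list(snp_ids)
    for l in range(path.n_lambda):
        nz = np.nonzero(path.coefs[:, l])[0]
        for j in nz:
            rows.append((path.lambdas[l], snp_ids[j], path.coefs[j, l]))
    pd.DataFrame(rows, columns=["lambda", "snp", "coefficient"]).to_csv(
        out_coefs, sep="\t", index=False
    )
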