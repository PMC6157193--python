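"""Nested k-fold cross-validation for the LASSO penalty and its assessment.

The outer loop measures out-of-sample prediction: each outer fold is held
out, the penalty lambda is chosen on the outer-training set alone by an
inner k-fold loop (minimum mean validation MSE over a shared lambda grid,
ties resolved toward the larger, more parsimonious lambda), the model is
refit on the full outer-training set at the chosen lambda, and the held-out
fold is predicted.  Pooled held-out predictions give the report metrics:
Pearson r (bounded by sqrt(h^2) for a heritability-h^2 trait), MSE, and the
slope of the best-fit line of predicted on observed (1 = perfect
prediction; heavy shrinkage drives it toward 0).  Because every sample is
predicted by a model that never saw it, the pooled r is unbiased at 0 under
the null — the signature advantage of nested over naive CV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lasso import LassoConfig, LassoPath, fit_path, lambda_grid, predict


@dataclass
class FoldAssignment:
    labels: np.ndarray  # per-sample fold label in 1..k
    k: int
    seed: int


@dataclass
class EvalMetrics:
    pearson_r: float
    mse: float
    slope: float
    degenerate: bool = False  # constant predictions; r and slope reported as 0


@dataclass
class FoldRecord:
    fold: int
    selected_lambda: float
    selected_index: int
    mean_mse_curve: np.ndarray
    test_index: np.ndarray
    predictions: np.ndarray
    coefs: np.ndarray  # full coefficient vector at the selected lambda
    intercept: float
    tracked_coefs: dict[int, float]
    converged: bool


@dataclass
class CVReport:
    folds: list[FoldRecord]
    pooled_predictions: np.ndarray  # aligned with the input sample order
    metrics: EvalMetrics
    lambda_range: tuple[float, float]
    tracked_mean: dict[int, float] = field(default_factory=dict)
    tracked_sd: dict[int, float] = field(default_factory=dict)
    fold_assignment: FoldAssignment | None = None

    def selected_lambdas(self) -> np.ndarray:
        return np.array([f.selected_lambda for f in self.folds])


def make_folds(n: int, k: int, seed: int = 0) -> FoldAssignment:
    """Uniformly random partition into k folds with sizes differing by <= 1."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    if k > n:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=np.int64)
    for f, chunk in enumerate(np.array_split(perm, k), start=1):
        labels[chunk] = f
    return FoldAssignment(labels=labels, k=k, seed=seed)


def evaluate(y_observed: np.ndarray, y_predicted: np.ndarray) -> EvalMetrics:
    """Pearson r, MSE and predicted-on-observed best-fit slope.

    Constant predictions are a degenerate case: r and slope are reported as
    0 with the flag set (correlation is undefined there).
    """
    y = np.asarray(y_observed, dtype=np.float64)
    yhat = np.asarray(y_predicted, dtype=np.float64)
    if y.shape != yhat.shape:
        raise ValueError("observed and predicted lengths differ")
    if y.size < 3:
        raise ValueError("need at least 3 observations")
    mse = float(np.mean((y - yhat) ** 2))
    vy = y - y.mean()
    vp = yhat - yhat.mean()
    denom_p = float(vp @ vp)
    denom_y = float(vy @ vy)
    if denom_p == 0 or denom_y == 0:
        return EvalMetrics(pearson_r=0.0, mse=mse, slope=0.0, degenerate=True)
    r = float(vy @ vp) / np.sqrt(denom_y * denom_p)
    slope = float(vy @ vp) / denom_y  # predicted regressed on observed
    return EvalMetrics(pearson_r=r, mse=mse, slope=slope)


def inner_select_lambda(
    X_train: np.ndarray,
    y_train: np.ndarray,
    k_inner: int,
    grid: np.ndarray,
    config: LassoConfig | None = None,
    seed: int = 0,
) -> tuple[int, float, np.ndarray, bool]:
    """Choose lambda on a training set by inner k-fold validation MSE.

    The grid is shared across inner splits (so the mean MSE per lambda is
    well defined).  Returns (index, lambda, mean MSE curve, all_converged);
    ties go to the first (largest) lambda attaining the minimum.
    """
    grid = np.asarray(grid, dtype=np.float64)
    if np.any(np.diff(grid) > 0):
        raise ValueError("lambda grid must be descending")
    if k_inner < 2:
        raise ValueError("need at least 2 inner folds")
    config = config or LassoConfig()
    n = X_train.shape[0]
    folds = make_folds(n, k_inner, seed=seed)
    mse = np.zeros((k_inner, len(grid)))
    all_converged = True
    for f in range(1, k_inner + 1):
        val = folds.labels == f
        fit = X_train[~val], y_train[~val]
        path = fit_path(fit[0], fit[1], config=config, lambdas=grid)
        all_converged &= bool(path.converged.all())
        Xv, yv = X_train[val], y_train[val]
        for l in range(len(grid)):
            resid = yv - predict(path, Xv, l)
            mse[f - 1, l] = float(np.mean(resid * resid))
    curve = mse.mean(axis=0)
    idx = int(np.argmin(curve))  # first minimum = largest lambda on ties
    return idx, float(grid[idx]), curve, all_converged


def nested_cv(
    X: np.ndarray,
    y: np.ndarray,
    k_outer: int = 10,
    k_inner: int = 10,
    config: LassoConfig | None = None,
    seed: int = 0,
    tracked_snps: list[int] | None = None,
) -> CVReport:
    """Nested cross-validation of the LASSO on (X, y).

    For each outer fold the lambda grid is recomputed from that fold's
    training set, the inner loop selects lambda, the model is refit on the
    full outer-training set (warm-started path down to the selection), and
    the held-out fold is predicted.  ``tracked_snps`` are column indices
    whose refit coefficients are summarized across folds (mean, n-1 SD).
    """
    X = np.asarray(X)
    y = np.asarray(y, dtype=np.float64)
    n = X.shape[0]
    if y.shape != (n,):
        raise ValueError("X and y dimensions are inconsistent")
    config = config or LassoConfig()
    tracked = list(tracked_snps or [])

    assignment = make_folds(n, k_outer, seed=seed)
    pooled = np.full(n, np.nan)
    records: list[FoldRecord] = []
    for f in range(1, k_outer + 1):
        test = assignment.labels == f
        X_tr, y_tr = X[~test], y[~test]
        grid = lambda_grid(X_tr, y_tr, config)
        idx, lam, curve, inner_ok = inner_select_lambda(
            X_tr, y_tr, k_inner, grid, config=config, seed=seed * 1000 + f
        )
        refit = fit_path(X_tr, y_tr, config=config, lambdas=grid[: idx + 1])
        b0, b = refit.coef_at(idx)
        test_idx = np.where(test)[0]
        preds = predict(refit, X[test_idx], idx)
        if np.any(~np.isnan(pooled[test_idx])):
            raise RuntimeError("outer folds overlap; leakage bookkeeping failed")
        pooled[test_idx] = preds
        records.append(
            FoldRecord(
                fold=f,
                selected_lambda=lam,
                selected_index=idx,
                mean_mse_curve=curve,
                test_index=test_idx,
                predictions=preds,
                coefs=b.copy(),
                intercept=b0,
                tracked_coefs={j: float(b[j]) for j in tracked},
                converged=inner_ok and bool(refit.converged.all()),
            )
        )

    if np.isnan(pooled).any():
        raise RuntimeError("pooled predictions do not cover every sample")
    metrics = evaluate(y, pooled)
    lams = np.array([r.selected_lambda for r in records])
    tracked_mean = {
        j: float(np.mean([r.tracked_coefs[j] for r in records])) for j in tracked
    }
    tracked_sd = {
        j: float(np.std([r.tracked_coefs[j] for r in records], ddof=1))
        if k_outer > 1
        else 0.0
        for j in tracked
    }
    return CVReport(
        folds=records,
        pooled_predictions=pooled,
        metrics=metrics,
        lambda_range=(float(lams.min()), float(lams.max())),
        tracked_mean=tracked_mean,
        tracked_sd=tracked_sd,
        fold_assignment=assignment,
    )


def report_to_dict(report: CVReport) -> dict:
    """JSON-serializable view of a CVReport (for the pipeline artifacts)."""
    return {
        "metrics": {
            "pearson_r": report.metrics.pearson_r,
            "mse": report.metrics.mse,
            "slope": report.metrics.slope,
            "degenerate": report.metrics.degenerate,
        },
        "lambda_range": list(report.lambda_range),
        "selected_lambdas": report.selected_lambdas().tolist(),
        "tracked_mean": {str(k): v for k, v in report.tracked_mean.items()},
        "tracked_sd": {str(k): v for k, v in report.tracked_sd.items()},
        "folds": [
            {
                "fold": r.fold,
                "selected_lambda": r.selected_lambda,
                "n_test": int(r.test_index.size),
                "n_nonzero": int(np.count_nonzero(r.coefs)),
                "tracked_coefs": {str(k): v for k, v in r.tracked_coefs.items()},
                "converged": r.converged,
            }
            for r in report.folds
        ],
    }
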