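"""Build the analysis phenotype from raw visit-level triglyceride data.

Pipeline: natural-log transform the four TG visits; average visits 1-2 into
a baseline and 3-4 into a follow-up (falling back to the single available
visit); regress the follow-up on baseline + age + center + smoking + the
top-k genotype principal components by OLS; return the standardized
residuals (mean 0, SD 1, n-1 denominator) as the final phenotype.  A Q-Q
table with the genomic-inflation factor supports the diagnostic that
stratification/relatedness are adequately absorbed by the PCs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .genotype_io import GenotypeMatrix

VISIT_COLS = ["tg_visit1", "tg_visit2", "tg_visit3", "tg_visit4"]

# median of the 1-df chi-square distribution; denominator of lambda_GC
CHI2_1DF_MEDIAN = float(chi2.ppf(0.5, df=1))  # 0.45493...


@dataclass
class PhenotypeVector:
    """Final analysis phenotype (standardized residuals) with drop audit."""

    sample_ids: list[str]
    values: np.ndarray
    dropped: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["sample_id", "reason"]))

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.values):
            raise ValueError("sample_ids / values length mismatch")


def build_baseline_followup(visits: pd.DataFrame) -> pd.DataFrame:
    """Per-sample baseline and follow-up log-TG means with single-visit fallback.

    Baseline = mean(ln v1, ln v2); if one of the two is missing, the other
    alone is used.  Follow-up likewise from v3/v4.  Samples with both
    baseline visits or both follow-up visits missing get NaN (and are
    dropped downstream with a recorded reason).
    """
    for c in VISIT_COLS:
        if c not in visits.columns:
            raise ValueError(f"visit table missing column {c}")
        vals = visits[c].to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] <= 0):
            raise ValueError(f"non-positive TG value in {c}")
    logs = np.log(visits[VISIT_COLS].to_numpy(dtype=float))
    with warnings.catch_warnings():
        # all-NaN visit pairs legitimately yield NaN (dropped downstream)
        warnings.simplefilter("ignore", category=RuntimeWarning)
        baseline = np.nanmean(logs[:, :2], axis=1)
        followup = np.nanmean(logs[:, 2:], axis=1)
    out = visits[["sample_id"]].copy() if "sample_id" in visits.columns else pd.DataFrame(
        {"sample_id": [f"sample_{i}" for i in range(len(visits))]})
    out["baseline"] = baseline
    out["followup"] = followup
    return out


def compute_pcs(G: GenotypeMatrix, k: int = 20) -> np.ndarray:
    """Top-k genotype principal-component scores, scaled to unit variance.

    Missing dosages are mean-imputed per SNP; columns are standardized
    (monomorphic ones dropped); scores are the left singular directions.
    Sign convention: the largest-magnitude loading of each component is
    positive.
    """
    X = G.dosages_float(impute_mean=True)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    Z = (X[:, keep] - mu[keep]) / sd[keep]
    n = Z.shape[0]
    if k > min(Z.shape):
        raise ValueError(f"k={k} exceeds matrix rank bound {min(Z.shape)}")
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    if np.sum(S > S[0] * 1e-12) < k:
        raise ValueError(f"k={k} exceeds numerical rank of the genotype matrix")
    # flip so the largest-|loading| entry of each right singular vector is positive
    for comp in range(k):
        j = np.argmax(np.abs(Vt[comp]))
        if Vt[comp, j] < 0:
            U[:, comp] = -U[:, comp]
            Vt[comp] = -Vt[comp]
    scores = U[:, :k] * np.sqrt(n)  # unit-variance scores (population SD)
    return scores


def adjust_phenotype(
    followup: np.ndarray,
    baseline: np.ndarray,
    covariates: pd.DataFrame,
    pcs: np.ndarray | None = None,
    sample_ids: list[str] | None = None,
) -> PhenotypeVector:
    """OLS-adjust follow-up for baseline + covariates (+ PCs); return
    standardized residuals.

    ``covariates`` must contain ``age`` (numeric), ``center`` (categorical,
    dummy-coded dropping the first level) and ``smoking`` (0/1).  Complete
    cases only; incomplete samples are dropped and recorded.  A
    rank-deficient design raises with the offending column named.
    """
    followup = np.asarray(followup, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    n = len(followup)
    if sample_ids is None:
        sample_ids = [f"sample_{i}" for i in range(n)]

    cols: dict[str, np.ndarray] = {"baseline": baseline}
    cols["age"] = covariates["age"].to_numpy(dtype=float)
    center = covariates["center"].astype("category")
    for lev in list(center.cat.categories)[1:]:
        cols[f"center_{lev}"] = (center == lev).to_numpy(dtype=float)
    cols["smoking"] = covariates["smoking"].to_numpy(dtype=float)
    if pcs is not None:
        pcs = np.asarray(pcs, dtype=float)
        for j in range(pcs.shape[1]):
            cols[f"pc{j + 1}"] = pcs[:, j]

    names = ["intercept"] + list(cols)
    design = np.column_stack([np.ones(n)] + [cols[c] for c in cols])
    complete = ~np.isnan(design).any(axis=1) & ~np.isnan(followup)
    dropped = pd.DataFrame(
        {
            "sample_id": [sid for sid, ok in zip(sample_ids, complete) if not ok],
            "reason": "incomplete_regressor_or_phenotype",
        }
    )
    D = design[complete]
    yv = followup[complete]
    if D.shape[0] <= D.shape[1]:
        raise ValueError("too few complete cases for the adjustment model")

    # locate rank deficiency before fitting so the error can name the column
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        for j in range(1, D.shape[1]):
            if np.linalg.matrix_rank(D[:, : j + 1]) < j + 1:
                raise ValueError(
                    f"design is rank-deficient: column '{names[j]}' is collinear "
                    "with the preceding regressors"
                )
    coef, *_ = np.linalg.lstsq(D, yv, rcond=None)
    resid = yv - D @ coef
    resid = resid - resid.mean()
    sd = resid.std(ddof=1)
    if sd == 0:
        raise ValueError("residuals are constant; cannot standardize")
    values = resid / sd
    kept_ids = [sid for sid, ok in zip(sample_ids, complete) if ok]
    return PhenotypeVector(sample_ids=kept_ids, values=values, dropped=dropped)


def prepare_phenotype(
    visits: pd.DataFrame,
    G: GenotypeMatrix | None = None,
    n_pcs: int = 20,
) -> PhenotypeVector:
    """Full phenotype construction from a raw visit table (convenience).

    Samples losing all baseline or all follow-up visits are dropped with a
    recorded reason before the adjustment stage.
    """
    bf = build_baseline_followup(visits)
    missing_base = np.isnan(bf["baseline"].to_numpy())
    missing_fu = np.isnan(bf["followup"].to_numpy())
    reasons = np.where(
        missing_base & missing_fu, "no_baseline_and_no_followup",
        np.where(missing_base, "no_baseline_visits",
                 np.where(missing_fu, "no_followup_visits", "")),
    )
    keep = reasons == ""
    dropped_visits = pd.DataFrame(
        {"sample_id": bf.loc[~keep, "sample_id"], "reason": reasons[~keep]}
    )

    idx = np.where(keep)[0]
    pcs = None
    if G is not None and n_pcs > 0:
        pcs = compute_pcs(G.subset_samples(idx), k=n_pcs)
    kept_ids = [bf["sample_id"].iloc[i] for i in idx]
    pheno = adjust_phenotype(
        bf["followup"].to_numpy()[idx],
        bf["baseline"].to_numpy()[idx],
        visits.iloc[idx][["age", "center", "smoking"]].reset_index(drop=True),
        pcs=pcs,
        sample_ids=kept_ids,
    )
    pheno.dropped = pd.concat([dropped_visits, pheno.dropped], ignore_index=True)
    return pheno


def qq_diagnostic(pvalues: np.ndarray) -> tuple[pd.DataFrame, float]:
    """Q-Q table of expected vs observed -log10 p plus lambda_GC.

    Expected quantile for rank i of m is -log10((i - 0.5) / m); the
    genomic-inflation factor is the median 1-df chi-square quantile of the
    p-values divided by the null median 0.4549.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.sort(p)
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    observed = -np.log10(order)
    table = pd.DataFrame({"expected_neglog10": expected, "observed_neglog10": observed})
    lambda_gc = float(np.median(chi2.isf(p, df=1)) / CHI2_1DF_MEDIAN)
    return table, lambda_gc
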