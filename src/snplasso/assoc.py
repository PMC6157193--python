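"""Per-SNP simple linear regression of phenotype on dosage.

Association runs on the final (already covariate-adjusted) phenotype with
no per-SNP covariates, matching the two-stage residual design: slope,
standard error, t statistic and a two-sided p-value on n-2 degrees of
freedom per SNP, handled complete-case per SNP.  Output feeds the Manhattan
table, LD clumping and the per-fold OLS comparator for the shrinkage
analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .genotype_io import MISSING, GenotypeMatrix

GENOME_WIDE_SIGNIFICANCE = 5e-8  # conventional threshold for the Manhattan line


def single_snp_regression(G: GenotypeMatrix, y: np.ndarray) -> pd.DataFrame:
    """OLS of y on each SNP's dosage, one SNP at a time.

    Returns a table aligned with the genotype columns: snp, chrom, pos,
    beta, se, tstat, p, n_used.  Monomorphic (or <3-observation) SNPs are
    flagged with beta = 0, p = 1.  p-values that underflow are floored at
    the smallest positive float.
    """
    y = np.asarray(y, dtype=np.float64)
    n, p = G.shape
    if y.shape != (n,):
        raise ValueError("phenotype length does not match genotype rows")

    X = G.dosages.astype(np.float64)
    obs = G.dosages != MISSING
    X[~obs] = 0.0
    yy = np.where(np.isnan(y), 0.0, y)
    y_obs = obs & ~np.isnan(y)[:, None]
    X[~y_obs] = 0.0

    n_used = y_obs.sum(axis=0).astype(np.float64)
    sx = X.sum(axis=0)  # X is zeroed outside the per-SNP complete-case mask
    sy = yy @ y_obs
    sxx = np.einsum("ij,ij->j", X, X)
    sxy = yy @ X
    syy = (yy * yy) @ y_obs

    with np.errstate(divide="ignore", invalid="ignore"):
        ssx = sxx - sx * sx / n_used
        ssy = syy - sy * sy / n_used
        sxy_c = sxy - sx * sy / n_used
        beta = sxy_c / ssx
        rss = ssy - beta * sxy_c
        df = n_used - 2
        sigma2 = np.maximum(rss, 0.0) / df
        se = np.sqrt(sigma2 / ssx)
        tstat = beta / se

    bad = (n_used < 3) | ~(ssx > 0)
    beta = np.where(bad, 0.0, beta)
    se = np.where(bad, np.nan, se)
    tstat = np.where(bad, 0.0, tstat)
    pvals = np.ones(p)
    ok = ~bad
    with np.errstate(divide="ignore", invalid="ignore"):
        pvals[ok] = 2.0 * t_dist.sf(np.abs(tstat[ok]), df[ok])
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)

    return pd.DataFrame(
        {
            "snp": G.snp_meta["snp"].to_numpy(),
            "chrom": G.snp_meta["chrom"].to_numpy(),
            "pos": G.snp_meta["pos"].to_numpy(),
            "beta": beta,
            "se": se,
            "tstat": tstat,
            "p": pvals,
            "n_used": n_used.astype(int),
        }
    )


def per_fold_ols_estimate(
    G: GenotypeMatrix,
    y: np.ndarray,
    snp_id: str,
    folds: np.ndarray,
) -> tuple[float, float, np.ndarray]:
    """Mean and SD (n-1) of the single-SNP OLS slope across training folds.

    For each fold label f, fits the slope on all samples *not* in f (the
    outer-training set), mirroring how cross-validated LASSO coefficients
    are summarized.  Returns (mean, sd, per-fold slopes).
    """
    matches = np.where(G.snp_meta["snp"].to_numpy() == snp_id)[0]
    if matches.size == 0:
        raise KeyError(f"SNP {snp_id!r} not present")
    j = int(matches[0])
    x_all = G.dosages[:, j].astype(np.float64)
    obs_all = G.dosages[:, j] != MISSING
    y = np.asarray(y, dtype=np.float64)
    folds = np.asarray(folds)

    slopes = []
    for f in np.unique(folds):
        m = (folds != f) & obs_all
        x, yy = x_all[m], y[m]
        vx = x - x.mean()
        denom = float(vx @ vx)
        if denom == 0:
            raise ValueError(f"SNP {snp_id!r} monomorphic in training fold {f}")
        slopes.append(float(vx @ (yy - yy.mean())) / denom)
    slopes = np.asarray(slopes)
    sd = float(slopes.std(ddof=1)) if slopes.size > 1 else 0.0
    return float(slopes.mean()), sd, slopes


def manhattan_table(assoc: pd.DataFrame) -> pd.DataFrame:
    """Add a cumulative genome coordinate for Manhattan-style plotting."""
    out = assoc.copy()
    offset = 0
    cum = np.empty(len(out), dtype=float)
    for chrom in pd.unique(out["chrom"]):
        m = (out["chrom"] == chrom).to_numpy()
        pos = out.loc[m, "pos"].to_numpy(dtype=float)
        cum[m] = pos + offset
        offset += pos.max() if pos.size else 0
    out["cum_pos"] = cum
    out["neglog10_p"] = -np.log10(out["p"])
    return out
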