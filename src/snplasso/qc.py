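"""SNP-level quality control: MAF filter, Hardy-Weinberg exact test, call rate.

The default HWE test is the exact conditional test (sum over heterozygote
counts of genotype-configuration probabilities no larger than the observed
one, conditioning on the allele counts), computed in log space.  An
asymptotic chi-square variant is available for comparison.

Filters are applied in the fixed order MAF -> HWE -> call rate and each
removed SNP is attributed to the first rule it fails, so the per-rule
removal counts always reconcile with the input count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from .genotype_io import MISSING, GenotypeMatrix


def minor_allele_freq(column: np.ndarray) -> float:
    """Minor allele frequency of a dosage vector, missing entries excluded.

    f = sum(dosages) / (2 * n_nonmissing); returns min(f, 1-f).
    """
    column = np.asarray(column)
    obs = column[column != MISSING]
    if obs.size == 0:
        raise ValueError("all-missing dosage column has no allele frequency")
    f = float(obs.sum()) / (2.0 * obs.size)
    return min(f, 1.0 - f)


def call_rate(column: np.ndarray) -> float:
    column = np.asarray(column)
    return float(np.mean(column != MISSING))


def genotype_counts(column: np.ndarray) -> tuple[int, int, int]:
    """(hom A1, het, hom A2) counts of a dosage column, missing excluded."""
    column = np.asarray(column)
    return (
        int(np.sum(column == 2)),
        int(np.sum(column == 1)),
        int(np.sum(column == 0)),
    )


def _log_het_probs(n_a: int, n_total: int) -> tuple[np.ndarray, np.ndarray]:
    """Log conditional probabilities of each feasible heterozygote count.

    Conditions on ``n_a`` copies of the rarer allele among ``2 * n_total``
    alleles.  Returns (het counts, log probabilities); the het count must
    share parity with n_a.
    """
    n_b = 2 * n_total - n_a
    hets = np.arange(n_a % 2, n_a + 1, 2)
    hom_a = (n_a - hets) // 2
    hom_b = (n_b - hets) // 2
    logp = (
        hets * np.log(2.0)
        + gammaln(n_total + 1)
        - gammaln(hom_a + 1)
        - gammaln(hets + 1)
        - gammaln(hom_b + 1)
        + gammaln(n_a + 1)
        + gammaln(n_b + 1)
        - gammaln(2 * n_total + 1)
    )
    return hets, logp


def hwe_exact_p(n_hom_a1: int, n_het: int, n_hom_a2: int) -> float:
    """Exact two-sided Hardy-Weinberg p-value from genotype counts.

    Sums, over all heterozygote counts consistent with the observed allele
    counts, the conditional probabilities that do not exceed the observed
    configuration's probability.  Monomorphic markers return 1.
    """
    for c in (n_hom_a1, n_het, n_hom_a2):
        if c < 0:
            raise ValueError("genotype counts must be non-negative")
    n_total = n_hom_a1 + n_het + n_hom_a2
    if n_total < 1:
        raise ValueError("need at least one genotyped sample")

    n_a = 2 * min(n_hom_a1, n_hom_a2) + n_het  # rarer allele count
    if n_a == 0:
        return 1.0
    hets, logp = _log_het_probs(n_a, n_total)
    log_obs = logp[np.searchsorted(hets, n_het)]
    # sum P(config) over configs with P <= P(observed); tiny slack absorbs
    # round-off so the observed configuration always counts itself
    keep = logp <= log_obs + 1e-12
    m = logp[keep].max()
    p = float(np.exp(m) * np.sum(np.exp(logp[keep] - m)))
    return min(p, 1.0)


def hwe_chisq_p(n_hom_a1: int, n_het: int, n_hom_a2: int) -> float:
    """Asymptotic 1-df chi-square Hardy-Weinberg p-value (comparison option)."""
    n = n_hom_a1 + n_het + n_hom_a2
    if n < 1:
        raise ValueError("need at least one genotyped sample")
    f = (2 * n_hom_a1 + n_het) / (2 * n)
    exp = np.array([f * f, 2 * f * (1 - f), (1 - f) * (1 - f)]) * n
    if np.any(exp == 0):
        return 1.0
    obs = np.array([n_hom_a1, n_het, n_hom_a2])
    stat = float(np.sum((obs - exp) ** 2 / exp))
    return float(chi2.sf(stat, df=1))


@dataclass
class QCReport:
    """Auditable per-SNP QC outcome plus reconciling totals."""

    n_input_snps: int
    n_removed_maf: int
    n_removed_hwe: int
    n_removed_callrate: int
    n_retained: int
    table: pd.DataFrame  # snp, maf, hwe_p, call_rate, verdict

    def __post_init__(self) -> None:
        total = (
            self.n_removed_maf
            + self.n_removed_hwe
            + self.n_removed_callrate
            + self.n_retained
        )
        if total != self.n_input_snps:
            raise ValueError("QC report counts do not reconcile")

    def summary(self) -> dict:
        return {
            "n_input_snps": self.n_input_snps,
            "n_removed_maf": self.n_removed_maf,
            "n_removed_hwe": self.n_removed_hwe,
            "n_removed_callrate": self.n_removed_callrate,
            "n_retained": self.n_retained,
        }


def apply_qc(
    G: GenotypeMatrix,
    maf_threshold: float = 0.01,
    hwe_threshold: float = 1e-5,
    callrate_threshold: float = 0.0,
    hwe_test: str = "exact",
) -> tuple[GenotypeMatrix, QCReport]:
    """Filter SNPs by MAF (strict <), HWE (p <= threshold), then call rate.

    Column order of survivors is preserved.  ``hwe_test`` is "exact"
    (default) or "chisq".
    """
    for name, thr in (
        ("maf_threshold", maf_threshold),
        ("hwe_threshold", hwe_threshold),
        ("callrate_threshold", callrate_threshold),
    ):
        if not 0.0 <= thr <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {thr}")
    hwe_fn = {"exact": hwe_exact_p, "chisq": hwe_chisq_p}[hwe_test]

    p = G.n_snps
    mafs = np.empty(p)
    hwe_ps = np.empty(p)
    rates = np.empty(p)
    verdicts = np.empty(p, dtype=object)
    for j in range(p):
        col = G.dosages[:, j]
        mafs[j] = minor_allele_freq(col)
        hwe_ps[j] = hwe_fn(*genotype_counts(col))
        rates[j] = call_rate(col)
        if mafs[j] < maf_threshold:
            verdicts[j] = "removed_maf"
        elif hwe_ps[j] <= hwe_threshold:
            verdicts[j] = "removed_hwe"
        elif rates[j] < callrate_threshold:
            verdicts[j] = "removed_callrate"
        else:
            verdicts[j] = "retained"

    table = pd.DataFrame(
        {
            "snp": G.snp_meta["snp"].to_numpy(),
            "maf": mafs,
            "hwe_p": hwe_ps,
            "call_rate": rates,
            "verdict": verdicts,
        }
    )
    keep = np.where(verdicts == "retained")[0]
    report = QCReport(
        n_input_snps=p,
        n_removed_maf=int(np.sum(verdicts == "removed_maf")),
        n_removed_hwe=int(np.sum(verdicts == "removed_hwe")),
        n_removed_callrate=int(np.sum(verdicts == "removed_callrate")),
        n_retained=len(keep),
        table=table,
    )
    return G.subset_snps(keep), report
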