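"""Synthetic genotypes, heritability-controlled phenotypes and visit tables.

The generators provide data with the statistical structure the analysis
stages assume, so the whole pipeline is testable without access to any
cohort data:

* genotypes in Hardy-Weinberg proportions, optionally organized in LD
  blocks where non-anchor alleles copy the block anchor's alleles with a
  given probability (realized allelic correlation ~ copy probability, so
  dosage r^2 ~ copy_prob^2 — direct, testable control of LD for clumping);
* a quantitative phenotype driven by one (or several) causal SNPs, with the
  environmental noise variance solved from the requested narrow-sense
  heritability h^2 so that corr(phenotype, genetic value) -> sqrt(h^2);
* a 4-visit triglyceride-style raw phenotype (log-normal, with age / center
  / smoking covariates and a treatment shift between visits 2 and 3) for
  exercising the phenotype-construction stage end to end.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix


@dataclass
class GenoSimConfig:
    n_individuals: int
    n_snps: int
    maf_low: float = 0.05
    maf_high: float = 0.5
    ld_block_size: int = 1  # 1 = independent SNPs
    ld_copy_prob: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0
    n_chromosomes: int = 1
    spacing_bp: int = 10_000

    def __post_init__(self) -> None:
        if self.n_individuals <= 0 or self.n_snps <= 0:
            raise ValueError("n_individuals and n_snps must be positive")
        if not (0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if not 0 <= self.ld_copy_prob < 1:
            raise ValueError("ld_copy_prob must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class CausalSpec:
    """Causal architecture: one SNP (or a list) with raw-dosage-scale effects.

    ``beta`` is the phenotype change per copy of the A1 allele on the raw
    0/1/2 scale; ``h2`` is the narrow-sense heritability the noise variance
    is solved from.
    """

    snp_index: int = 0
    beta: float = -0.44
    h2: float = 0.05
    extra: list[tuple[int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 <= self.h2 < 1:
            raise ValueError("h2 must be in [0, 1)")

    def effects(self) -> list[tuple[int, float]]:
        return [(self.snp_index, self.beta)] + list(self.extra)


@dataclass
class VisitSimConfig:
    age_effect: float = 0.004  # per year of age, log-TG scale
    center_effect: float = 0.05  # center B vs A
    smoking_effect: float = 0.08
    baseline_mean: float = 4.6  # log of ~100 mg/dL
    baseline_sd: float = 0.45  # between-subject SD of log-TG
    treatment_shift: float = -0.25  # log-TG drop after lipid-lowering drug
    visit_noise_sd: float = 0.15  # within-subject, per visit
    missing_prob: float = 0.05  # per visit, independent
    n_centers: int = 2
    smoking_prevalence: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("baseline_sd", "visit_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.missing_prob < 1:
            raise ValueError("missing_prob must be in [0, 1)")


def simulate_genotypes(config: GenoSimConfig) -> GenotypeMatrix:
    """Genotypes in HWE with optional fixed-size LD blocks.

    Each block's anchor SNP is Binomial(2, maf) per individual with
    maf ~ Uniform(maf_low, maf_high); every non-anchor allele in the block
    copies the corresponding anchor allele with probability ``ld_copy_prob``
    and is otherwise a fresh Bernoulli(maf) draw.  The last block truncates
    at p.  Missingness is applied MCAR at ``missing_rate``.
    """
    rng = np.random.default_rng(config.seed)
    n, p = config.n_individuals, config.n_snps
    bs = config.ld_block_size
    dosages = np.empty((n, p), dtype=np.int8)
    mafs = np.empty(p)
    for start in range(0, p, bs):
        width = min(bs, p - start)
        maf = rng.uniform(config.maf_low, config.maf_high)
        mafs[start : start + width] = maf
        anchor = rng.binomial(1, maf, size=(n, 2)).astype(np.int8)
        dosages[:, start] = anchor.sum(axis=1)
        for off in range(1, width):
            copy = rng.random(size=(n, 2)) < config.ld_copy_prob
            fresh = rng.binomial(1, maf, size=(n, 2)).astype(np.int8)
            alleles = np.where(copy, anchor, fresh)
            dosages[:, start + off] = alleles.sum(axis=1)
    if config.missing_rate > 0:
        miss = rng.random(size=(n, p)) < config.missing_rate
        dosages[miss] = MISSING

    per_chrom = -(-p // config.n_chromosomes)
    idx = np.arange(p)
    meta = pd.DataFrame(
        {
            "snp": [f"snp_{j}" for j in idx],
            "chrom": (idx // per_chrom + 1).astype(str),
            "pos": (idx % per_chrom + 1) * config.spacing_bp,
            "a1": "A",
            "a2": "B",
        }
    )
    meta["sim_maf"] = mafs
    return GenotypeMatrix(
        dosages=dosages,
        snp_meta=meta,
        sample_ids=[f"ind_{i}" for i in range(n)],
    )


def noise_variance_for_h2(beta: float, maf: float, h2: float) -> float:
    """Environmental variance giving heritability ``h2`` for one causal SNP.

    Under HWE the genetic variance is beta^2 * 2 * maf * (1 - maf), so
    sigma^2 = beta^2 * 2 maf (1 - maf) * (1 - h2) / h2.
    """
    if not 0 < maf < 1:
        raise ValueError("maf must be in (0, 1)")
    if h2 <= 0:
        raise ValueError("h2 = 0 leaves the noise variance undefined")
    if h2 >= 1:
        raise ValueError("h2 must be < 1")
    if beta == 0:
        raise ValueError("beta = 0 cannot produce positive heritability")
    var_g = beta * beta * 2.0 * maf * (1.0 - maf)
    return var_g * (1.0 - h2) / h2


def simulate_phenotype(
    G: GenotypeMatrix,
    causal: CausalSpec,
    seed: int = 0,
    noise_sd: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Quantitative phenotype y = sum_c beta_c g_c + e, e ~ N(0, sigma^2).

    The noise variance is solved from ``causal.h2`` using each causal
    column's **empirical** allele frequency (summing variance contributions
    over causal SNPs).  Missing causal dosages are imputed at 2f.  Passing
    ``noise_sd`` overrides the solved value (test hook; 0 gives the
    noiseless h2 -> 1 limit).

    Returns (y, genetic_values); the latter are the noiseless genetic values
    for diagnostics.
    """
    rng = np.random.default_rng(seed)
    n = G.n_samples
    genetic = np.zeros(n)
    var_g_total = 0.0
    for idx, beta in causal.effects():
        if not 0 <= idx < G.n_snps:
            raise IndexError(f"causal snp_index {idx} out of range")
        col = G.dosages[:, idx].astype(np.float64)
        obs = col[G.dosages[:, idx] != MISSING]
        if obs.size == 0 or obs.min() == obs.max():
            raise ValueError(f"causal column {idx} is monomorphic")
        f = obs.mean() / 2.0
        col[G.dosages[:, idx] == MISSING] = 2.0 * f
        genetic += beta * col
        var_g_total += beta * beta * 2.0 * f * (1.0 - f)
    if noise_sd is None:
        if causal.h2 <= 0:
            raise ValueError("h2 must be > 0 (or pass noise_sd explicitly)")
        sigma2 = var_g_total * (1.0 - causal.h2) / causal.h2
        noise_sd = float(np.sqrt(sigma2))
    y = genetic + rng.normal(0.0, noise_sd, size=n)
    return y, genetic


def simulate_visits(
    G: GenotypeMatrix,
    causal: CausalSpec,
    config: VisitSimConfig,
) -> pd.DataFrame:
    """Raw-scale 4-visit TG table with covariates.

    Visits 1-2 are pre-treatment, 3-4 post-treatment; the causal genetic
    effect is injected into the post-treatment log-TG change, so it is
    recoverable as an effect on the follow-up measure adjusted for baseline.
    Values are exponentiated log-TG (always positive); per-visit missingness
    is independent.
    """
    rng = np.random.default_rng(config.seed)
    n = G.n_samples
    age = rng.uniform(20.0, 70.0, size=n)
    center = rng.integers(0, config.n_centers, size=n)
    smoking = rng.binomial(1, config.smoking_prevalence, size=n)

    _, genetic = simulate_phenotype(G, causal, seed=config.seed + 1, noise_sd=0.0)

    latent = (
        config.baseline_mean
        + config.age_effect * (age - 45.0)
        + config.center_effect * (center > 0).astype(float)
        + config.smoking_effect * smoking
        + rng.normal(0.0, config.baseline_sd, size=n)
    )
    followup_latent = latent + config.treatment_shift + genetic

    out = {"sample_id": G.sample_ids, "age": age, "center": center, "smoking": smoking}
    for v, lat in zip((1, 2, 3, 4), (latent, latent, followup_latent, followup_latent)):
        noise = rng.normal(0.0, config.visit_noise_sd, size=n)
        vals = np.exp(lat + noise)
        if config.missing_prob > 0:
            vals = np.where(rng.random(n) < config.missing_prob, np.nan, vals)
        out[f"tg_visit{v}"] = vals
    return pd.DataFrame(out)


def single_causal_study(
    n: int,
    p: int,
    beta: float = -0.44,
    h2: float = 0.05,
    causal_maf: float = 0.3,
    causal_index: int | None = None,
    seed: int = 0,
    geno_config: GenoSimConfig | None = None,
) -> tuple[GenotypeMatrix, np.ndarray, np.ndarray, int]:
    """One-causal-SNP study data set: genotypes, phenotype, genetic values.

    Genotypes follow ``geno_config`` (default: independent SNPs, maf uniform
    on (0.05, 0.5)); the causal column is regenerated at ``causal_maf``
    (default 0.3, a mid-range frequency) so its frequency is controlled.
    Returns (G, y, genetic_values, causal_index).
    """
    cfg = geno_config or GenoSimConfig(n_individuals=n, n_snps=p, seed=seed)
    G = simulate_genotypes(cfg)
    rng = np.random.default_rng(seed + 1)
    if causal_index is None:
        causal_index = p // 2
    G.dosages[:, causal_index] = rng.binomial(2, causal_maf, size=n).astype(np.int8)
    causal = CausalSpec(snp_index=causal_index, beta=beta, h2=h2)
    y, genetic = simulate_phenotype(G, causal, seed=seed + 2)
    return G, y, genetic, causal_index


def write_simulation(
    G: GenotypeMatrix,
    y: np.ndarray,
    out_dir: str | Path,
    params: dict,
    prefix: str = "sim",
) -> None:
    """Write PLINK files, a phenotype TSV and a JSON parameter sidecar."""
    from .genotype_io import write_plink_bed

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_plink_bed(G, out_dir / prefix)
    pd.DataFrame({"sample_id": G.sample_ids, "phenotype": y}).to_csv(
        out_dir / f"{prefix}_phenotype.tsv", sep="\t", index=False
    )
    with open(out_dir / f"{prefix}_params.json", "w") as fh:
        json.dump(params, fh, indent=2, default=str)
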