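"""Config-driven end-to-end run: simulate -> QC -> phenotype -> association
-> clumping -> nested cross-validation.

Every stage writes its artifact into the run directory, a log records the
per-stage sample/SNP counts (inputs reconcile with retained + removed at
every stage), and the global seed propagates deterministically, so a rerun
with the same config reproduces all outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc as assoc_mod
from . import clump as clump_mod
from . import phenotype_prep, qc, synthetic_data
from .genotype_io import write_plink_bed
from .lasso import LassoConfig
from .nested_cv import nested_cv as run_nested_cv
from .nested_cv import report_to_dict


@dataclass
class PipelineConfig:
    # simulation
    n_individuals: int = 400
    n_snps: int = 1000
    maf_low: float = 0.05
    maf_high: float = 0.5
    ld_block_size: int = 1
    ld_copy_prob: float = 0.0
    missing_rate: float = 0.0
    causal_beta: float = -0.44
    causal_h2: float = 0.05
    causal_maf: float = 0.3
    phenotype_mode: str = "direct"  # "direct" (y = beta g + e) or "visits"
    n_pcs: int = 0  # PCs used in the visits-mode adjustment
    # qc
    run_qc: bool = True
    maf_threshold: float = 0.01
    hwe_threshold: float = 1e-5
    callrate_threshold: float = 0.0
    # clumping
    run_clump: bool = True
    clump_r2: float = 0.5
    clump_kb: float = 250.0
    clump_p1: float = 1.0
    clump_p2: float = 1.0
    # nested CV
    k_outer: int = 10
    k_inner: int = 10
    n_lambda: int = 100
    lambda_min_ratio: float | None = None
    tol: float = 1e-7
    screen: bool = False
    # global
    seed: int = 0
    out_dir: str = "snplasso_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


PRESETS: dict[str, dict] = {
    # GAW20-scale cohort: a few hundred individuals, weak polygenic signal
    "gaw20-like": dict(
        n_individuals=680, n_snps=56_000, phenotype_mode="visits", n_pcs=20,
        k_inner=5, n_lambda=50, screen=True,
    ),
    # one causal SNP, beta=-0.44, h2=0.05 at the small and the large sample size
    "illustrative-n700": dict(
        n_individuals=700, n_snps=56_000, k_inner=5, n_lambda=50, screen=True,
    ),
    "illustrative-n7753": dict(
        n_individuals=7753, n_snps=56_000, k_inner=5, n_lambda=50, screen=True,
    ),
}


def preset_config(name: str, **overrides) -> PipelineConfig:
    params = dict(PRESETS[name])
    params.update(overrides)
    return PipelineConfig(**params)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all enabled stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    try:
        # ---- stage: simulate ------------------------------------------------
        geno_cfg = synthetic_data.GenoSimConfig(
            n_individuals=config.n_individuals,
            n_snps=config.n_snps,
            maf_low=config.maf_low,
            maf_high=config.maf_high,
            ld_block_size=config.ld_block_size,
            ld_copy_prob=config.ld_copy_prob,
            missing_rate=config.missing_rate,
            seed=config.seed,
        )
        G = synthetic_data.simulate_genotypes(geno_cfg)
        rng = np.random.default_rng(config.seed + 1)
        causal_index = config.n_snps // 2
        G.dosages[:, causal_index] = rng.binomial(
            2, config.causal_maf, size=config.n_individuals
        ).astype(np.int8)
        causal = synthetic_data.CausalSpec(
            snp_index=causal_index, beta=config.causal_beta, h2=config.causal_h2
        )
        causal_snp = G.snp_meta["snp"].iloc[causal_index]
        write_plink_bed(G, out / "genotypes")
        log(f"simulate: {G.n_samples} samples x {G.n_snps} SNPs, "
            f"causal {causal_snp} (beta={config.causal_beta}, h2={config.causal_h2})")

        if config.phenotype_mode == "visits":
            visit_cfg = synthetic_data.VisitSimConfig(seed=config.seed + 2)
            visits = synthetic_data.simulate_visits(G, causal, visit_cfg)
            visits.to_csv(out / "visits.tsv", sep="\t", index=False)
        else:
            y, genetic = synthetic_data.simulate_phenotype(
                G, causal, seed=config.seed + 2
            )

        # ---- stage: qc ------------------------------------------------------
        if config.run_qc:
            G_qc, report = qc.apply_qc(
                G,
                maf_threshold=config.maf_threshold,
                hwe_threshold=config.hwe_threshold,
                callrate_threshold=config.callrate_threshold,
            )
            report.table.to_csv(out / "qc_report.tsv", sep="\t", index=False)
            (out / "qc_summary.json").write_text(json.dumps(report.summary(), indent=2))
            s = report.summary()
            log(f"qc: {s['n_input_snps']} in = {s['n_removed_maf']} maf + "
                f"{s['n_removed_hwe']} hwe + {s['n_removed_callrate']} callrate + "
                f"{s['n_retained']} retained")
            if causal_snp not in set(G_qc.snp_meta["snp"]):
                raise RuntimeError("causal SNP removed by QC; adjust thresholds")
            G = G_qc
            causal_index = int(
                np.where(G.snp_meta["snp"].to_numpy() == causal_snp)[0][0]
            )

        # ---- stage: phenotype ----------------------------------------------
        if config.phenotype_mode == "visits":
            pheno = phenotype_prep.prepare_phenotype(visits, G=G, n_pcs=config.n_pcs)
            kept = [G.sample_ids.index(s) for s in pheno.sample_ids]
            G = G.subset_samples(np.array(kept, dtype=int))
            y = pheno.values
            log(f"phenotype: {len(pheno.values)} retained, "
                f"{len(pheno.dropped)} dropped")
            pheno.dropped.to_csv(out / "phenotype_dropped.tsv", sep="\t", index=False)
        else:
            log(f"phenotype: direct simulation, n={len(y)}, "
                f"corr(y, genetic)={np.corrcoef(y, genetic)[0, 1]:.4f}")
        pd.DataFrame({"sample_id": G.sample_ids, "phenotype": y}).to_csv(
            out / "phenotype.tsv", sep="\t", index=False
        )

        # ---- stage: association --------------------------------------------
        table = assoc_mod.single_snp_regression(G, y)
        assoc_mod.manhattan_table(table).to_csv(
            out / "assoc.tsv", sep="\t", index=False
        )
        qq_table, lambda_gc = phenotype_prep.qq_diagnostic(table["p"].to_numpy())
        qq_table.to_csv(out / "qq.tsv", sep="\t", index=False)
        log(f"assoc: {len(table)} SNPs tested, min p = {table['p'].min():.3e}, "
            f"lambda_GC = {lambda_gc:.3f}")

        # ---- stage: clumping ------------------------------------------------
        if config.run_clump:
            cres = clump_mod.clump(
                table,
                G,
                clump_mod.ClumpConfig(
                    r2_threshold=config.clump_r2,
                    window_kb=config.clump_kb,
                    index_p_max=config.clump_p1,
                    member_p_max=config.clump_p2,
                ),
            )
            clump_mod.clump_table(cres).to_csv(
                out / "clumps.tsv", sep="\t", index=False
            )
            log(f"clump: {G.n_snps} in -> {len(cres.retained_cols)} retained")
            if causal_snp not in set(cres.retained_snps):
                raise RuntimeError("causal SNP clumped away; it should index its clump")
            G = G.subset_snps(cres.retained_cols)
            causal_index = int(
                np.where(G.snp_meta["snp"].to_numpy() == causal_snp)[0][0]
            )

        # ---- stage: nested CV ----------------------------------------------
        lcfg = LassoConfig(
            n_lambda=config.n_lambda,
            lambda_min_ratio=config.lambda_min_ratio,
            tol=config.tol,
            screen=config.screen,
        )
        X = G.dosages_float(dtype=np.float32, impute_mean=True)
        report = run_nested_cv(
            X,
            np.asarray(y, dtype=np.float64),
            k_outer=config.k_outer,
            k_inner=config.k_inner,
            config=lcfg,
            seed=config.seed + 3,
            tracked_snps=[causal_index],
        )
        cv_dict = report_to_dict(report)
        cv_dict["causal_snp"] = str(causal_snp)
        cv_dict["causal_index_post_filter"] = causal_index
        (out / "cv_report.json").write_text(json.dumps(cv_dict, indent=2))
        pd.DataFrame(
            {
                "sample_id": G.sample_ids,
                "observed": y,
                "predicted": report.pooled_predictions,
            }
        ).to_csv(out / "cv_predictions.tsv", sep="\t", index=False)
        m = report.metrics
        log(f"nested_cv: r={m.pearson_r:.4f} mse={m.mse:.4f} slope={m.slope:.4f} "
            f"lambda range [{report.lambda_range[0]:.4g}, {report.lambda_range[1]:.4g}] "
            f"causal coef mean={report.tracked_mean[causal_index]:.4f} "
            f"sd={report.tracked_sd[causal_index]:.4f}")
    except Exception as exc:
        stage = log_lines[-1].split(":")[0] if log_lines else "simulate"
        (out / "log.txt").write_text("\n".join(log_lines) + f"\nFAILED after stage "
                                     f"'{stage}': {exc}\n")
        raise RuntimeError(f"pipeline failed after stage '{stage}': {exc}") from exc

    (out / "config.yaml").write_text(yaml.safe_dump(dataclasses.asdict(config)))
    (out / "log.txt").write_text("\n".join(log_lines) + "\n")
    return out
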