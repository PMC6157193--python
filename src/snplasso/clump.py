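"""Greedy LD-based clumping: one representative SNP per correlated group.

SNPs are ranked by association p-value (ties broken by position, then id);
the best-ranked unassigned SNP seeds a clump and absorbs every unassigned
SNP on the same chromosome within the physical window whose dosage r^2
with it meets the threshold.  Index SNPs plus never-eligible SNPs are
retained, reducing dimensionality before the penalized fit while keeping
one tag per LD group.  r^2 is the squared Pearson correlation of dosages
over pairwise-complete samples (genotypic LD; no phasing required).
Cross-chromosome pairs never clump.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix


@dataclass
class ClumpConfig:
    r2_threshold: float = 0.5
    window_kb: float = 250.0
    index_p_max: float = 1.0  # 1.0: every SNP may seed (pure dimension reduction)
    member_p_max: float = 1.0

    def __post_init__(self) -> None:
        for name in ("r2_threshold", "index_p_max", "member_p_max"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.window_kb < 0:
            raise ValueError("window_kb must be >= 0")


@dataclass
class ClumpResult:
    clumps: list[dict]  # {"index_snp": id, "members": [ids]}
    retained_cols: np.ndarray  # original column order
    retained_snps: list[str]
    config: ClumpConfig = field(default_factory=ClumpConfig)


def pairwise_r2(col_a: np.ndarray, col_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage columns.

    Uses pairwise-complete samples; returns 0.0 if either column is
    monomorphic on the complete set (flagged case) or fewer than 2
    complete pairs exist.
    """
    a = np.asarray(col_a, dtype=np.float64)
    b = np.asarray(col_b, dtype=np.float64)
    m = (np.asarray(col_a) != MISSING) & (np.asarray(col_b) != MISSING)
    if m.sum() < 2:
        raise ValueError("need >= 2 pairwise-complete observations")
    a, b = a[m], b[m]
    va = a - a.mean()
    vb = b - b.mean()
    da = float(va @ va)
    db = float(vb @ vb)
    if da == 0 or db == 0:
        return 0.0
    r = float(va @ vb) / np.sqrt(da * db)
    return r * r


def clump(
    assoc: pd.DataFrame,
    G: GenotypeMatrix,
    config: ClumpConfig | None = None,
) -> ClumpResult:
    """Greedy p-value-ordered clumping of the association table.

    Rows of ``assoc`` must align with the columns of ``G``.  Deterministic:
    candidate order is (p ascending, position ascending, snp id).
    """
    config = config or ClumpConfig()
    if len(assoc) != G.n_snps:
        raise ValueError("association table does not align with genotype columns")

    p_vals = assoc["p"].to_numpy(dtype=float)
    pos = assoc["pos"].to_numpy(dtype=float)
    chrom = assoc["chrom"].to_numpy(dtype=str)
    snp_ids = assoc["snp"].to_numpy(dtype=str)
    order = np.lexsort((snp_ids, pos, p_vals))  # last key is primary

    window_bp = config.window_kb * 1000.0
    n_snps = G.n_snps
    assigned = np.zeros(n_snps, dtype=bool)
    is_index = np.zeros(n_snps, dtype=bool)
    member_eligible = p_vals <= config.member_p_max
    clumps: list[dict] = []

    # per-chromosome position-sorted index so each clump scans only its window
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in np.unique(chrom):
        cols = np.where(chrom == c)[0]
        cols = cols[np.argsort(pos[cols], kind="stable")]
        by_chrom[c] = (cols, pos[cols])

    for j in order:
        if assigned[j] or p_vals[j] > config.index_p_max:
            continue
        assigned[j] = True
        is_index[j] = True
        members = []
        cols, cpos = by_chrom[chrom[j]]
        lo = np.searchsorted(cpos, pos[j] - window_bp, side="left")
        hi = np.searchsorted(cpos, pos[j] + window_bp, side="right")
        for k in cols[lo:hi]:
            if assigned[k] or not member_eligible[k]:
                continue
            if pairwise_r2(G.dosages[:, j], G.dosages[:, k]) >= config.r2_threshold:
                assigned[k] = True
                members.append(snp_ids[k])
        clumps.append({"index_snp": snp_ids[j], "members": members})

    # retained = index SNPs plus SNPs never eligible for assignment
    retained_mask = is_index | ~assigned
    retained_cols = np.where(retained_mask)[0]
    return ClumpResult(
        clumps=clumps,
        retained_cols=retained_cols,
        retained_snps=[snp_ids[c] for c in retained_cols],
        config=config,
    )


def clump_table(result: ClumpResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "index_snp": [c["index_snp"] for c in result.clumps],
            "members": [",".join(c["members"]) for c in result.clumps],
            "clump_size": [1 + len(c["members"]) for c in result.clumps],
        }
    )
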