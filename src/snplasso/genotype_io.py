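"""Genotype containers and PLINK 1 / TSV dosage input-output.

Dosages count copies of the A1 allele (the first allele column of the
``.bim`` file, conventionally the minor allele), so a dosage of 2 means
homozygous A1.  Missing genotypes are coded :data:`MISSING` (-1) in the
integer matrix.  Base-pair positions are 1-based, as in ``.bim``;
chromosomes are stored as strings so "X"/"MT" need no special-casing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING: int = -1

_PLINK_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

# PLINK 1 2-bit code -> A1-allele dosage. 00=hom A1, 01=missing, 10=het, 11=hom A2.
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}

SNP_META_COLUMNS = ["snp", "chrom", "pos", "a1", "a2"]


@dataclass
class GenotypeMatrix:
    """n x p dosage matrix with per-SNP metadata and sample identifiers.

    Parameters
    ----------
    dosages:
        int8 array of shape (n_samples, n_snps) with entries in
        {0, 1, 2, MISSING}.
    snp_meta:
        DataFrame with columns ``snp, chrom, pos, a1, a2`` (one row per SNP).
    sample_ids:
        Length-n list of unique sample identifiers.
    """

    dosages: np.ndarray
    snp_meta: pd.DataFrame
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D array")
        n, p = self.dosages.shape
        if len(self.snp_meta) != p:
            raise ValueError(
                f"snp_meta has {len(self.snp_meta)} rows but matrix has {p} SNPs"
            )
        if not self.sample_ids:
            self.sample_ids = [f"sample_{i}" for i in range(n)]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match matrix rows")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids must be unique")
        if self.snp_meta["snp"].duplicated().any():
            raise ValueError("SNP ids must be unique")
        if (pd.to_numeric(self.snp_meta["pos"]) < 0).any():
            raise ValueError("positions must be non-negative")
        valid = np.isin(self.dosages, [0, 1, 2, MISSING])
        if not valid.all():
            bad = np.unique(self.dosages[~valid])
            raise ValueError(f"invalid dosage values: {bad.tolist()}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.dosages.shape

    def subset_snps(self, col_index: np.ndarray) -> "GenotypeMatrix":
        """Column subset preserving order of *col_index*."""
        col_index = np.asarray(col_index)
        return GenotypeMatrix(
            dosages=self.dosages[:, col_index].copy(),
            snp_meta=self.snp_meta.iloc[col_index].reset_index(drop=True),
            sample_ids=list(self.sample_ids),
        )

    def subset_samples(self, row_index: np.ndarray) -> "GenotypeMatrix":
        row_index = np.asarray(row_index)
        return GenotypeMatrix(
            dosages=self.dosages[row_index, :].copy(),
            snp_meta=self.snp_meta.copy(),
            sample_ids=[self.sample_ids[i] for i in row_index],
        )

    def dosages_float(self, dtype=np.float64, impute_mean: bool = False) -> np.ndarray:
        """Dosages as a float array, missing as NaN or column-mean imputed."""
        X = self.dosages.astype(dtype)
        miss = self.dosages == MISSING
        if miss.any():
            X[miss] = np.nan
            if impute_mean:
                col_means = np.nanmean(X, axis=0)
                col_means = np.where(np.isnan(col_means), 0.0, col_means)
                idx = np.where(miss)
                X[idx] = col_means[idx[1]]
        return X

    def __eq__(self, other) -> bool:  # matrix + metadata + ids
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            np.array_equal(self.dosages, other.dosages)
            and self.snp_meta.reset_index(drop=True).equals(
                other.snp_meta.reset_index(drop=True)
            )
            and self.sample_ids == other.sample_ids
        )


def read_plink_bed(path_prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK 1 ``.bed/.bim/.fam`` triple into a :class:`GenotypeMatrix`.

    Only SNP-major files (third byte 0x01) are supported; the legacy
    individual-major layout is rejected.
    """
    prefix = Path(path_prefix)
    bed_path = prefix.parent / (prefix.name + ".bed")
    bim_path = prefix.parent / (prefix.name + ".bim")
    fam_path = prefix.parent / (prefix.name + ".fam")
    for p in (bed_path, bim_path, fam_path):
        if not p.exists():
            raise FileNotFoundError(f"missing PLINK file: {p}")

    bim = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        fam_path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    n, p = len(fam), len(bim)

    raw = bed_path.read_bytes()
    if len(raw) < 3 or raw[:2] != _PLINK_MAGIC:
        raise ValueError(f"{bed_path}: not a PLINK 1 .bed file (bad magic bytes)")
    if raw[2] == 0x00:
        raise ValueError(
            f"{bed_path}: individual-major .bed files (mode byte 0x00) are not "
            "supported; convert to SNP-major"
        )
    if raw[2] != _SNP_MAJOR:
        raise ValueError(f"{bed_path}: unknown mode byte 0x{raw[2]:02x}")

    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * p
    if len(raw) != expected:
        raise ValueError(
            f"{bed_path}: truncated or oversized record ({len(raw)} bytes, "
            f"expected {expected} for {n} samples x {p} SNPs)"
        )

    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(p, bytes_per_snp)
    # unpack 2-bit codes, sample index advancing from the low bits of each byte
    codes = np.empty((p, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (data >> (2 * k)) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T.copy()

    meta = bim[["snp", "chrom", "pos", "a1", "a2"]].copy()
    return GenotypeMatrix(dosages=dosages, snp_meta=meta, sample_ids=list(fam["iid"]))


def write_plink_bed(G: GenotypeMatrix, path_prefix: str | Path) -> None:
    """Write SNP-major PLINK 1 ``.bed/.bim/.fam``; padding bits are zero."""
    if G.n_samples == 0 or G.n_snps == 0:
        raise ValueError("cannot write an empty genotype matrix")
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    n, p = G.shape
    bytes_per_snp = (n + 3) // 4
    lut = np.zeros(256, dtype=np.uint8)  # dosage byte (int8 view) -> 2-bit code
    for dos, code in _DOSAGE_TO_CODE.items():
        lut[np.uint8(np.int8(dos))] = code
    codes = lut[G.dosages.T.astype(np.int8).view(np.uint8)]  # p x n
    padded = np.zeros((p, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = codes
    out = np.zeros((p, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        out |= padded[:, k::4] << (2 * k)

    with open(prefix.parent / (prefix.name + ".bed"), "wb") as fh:
        fh.write(_PLINK_MAGIC + bytes([_SNP_MAJOR]))
        fh.write(out.tobytes())

    bim = pd.DataFrame(
        {
            "chrom": G.snp_meta["chrom"],
            "snp": G.snp_meta["snp"],
            "cm": 0,
            "pos": G.snp_meta["pos"],
            "a1": G.snp_meta["a1"],
            "a2": G.snp_meta["a2"],
        }
    )
    bim.to_csv(prefix.parent / (prefix.name + ".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": G.sample_ids,
            "iid": G.sample_ids,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.parent / (prefix.name + ".fam"), sep=" ", header=False, index=False)


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    """Read a TSV dosage matrix: header of SNP ids, first column sample ids.

    Missing dosages are encoded "NA".  SNP metadata is minimal (consecutive
    positions on chromosome "1") since the TSV format carries none.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError("dosage TSV needs a sample-id column and >= 1 SNP column")
    sample_ids = df.iloc[:, 0].tolist()
    snp_ids = list(df.columns[1:])
    cells = df.iloc[:, 1:].to_numpy()
    dosages = np.full(cells.shape, MISSING, dtype=np.int8)
    ok = np.zeros(cells.shape, dtype=bool)
    for val, dos in (("0", 0), ("1", 1), ("2", 2), ("NA", MISSING)):
        hit = cells == val
        dosages[hit] = dos
        ok |= hit
    if not ok.all():
        bad = np.unique(cells[~ok])
        raise ValueError(f"non-{{0,1,2,NA}} cells in dosage TSV: {bad.tolist()[:5]}")
    meta = pd.DataFrame(
        {
            "snp": snp_ids,
            "chrom": "1",
            "pos": np.arange(1, len(snp_ids) + 1) * 10_000,
            "a1": "A",
            "a2": "B",
        }
    )
    return GenotypeMatrix(dosages=dosages, snp_meta=meta, sample_ids=sample_ids)


def write_dosage_tsv(G: GenotypeMatrix, path: str | Path) -> None:
    """Write dosages as TSV (header: sample_id + SNP ids; missing -> NA)."""
    cells = G.dosages.astype(object)
    cells[G.dosages == MISSING] = "NA"
    df = pd.DataFrame(cells, columns=G.snp_meta["snp"].tolist())
    df.insert(0, "sample_id", G.sample_ids)
    df.to_csv(path, sep="\t", index=False)
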