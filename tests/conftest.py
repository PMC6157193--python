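import numpy as np
import pandas as pd
import pytest

from snplasso.genotype_io import GenotypeMatrix


def make_matrix(dosages, chrom=None, pos=None, sample_ids=None) -> GenotypeMatrix:
    """GenotypeMatrix from a plain array with auto-generated metadata."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, p = dosages.shape
    meta = pd.DataFrame(
        {
            "snp": [f"snp_{j}" for j in range(p)],
            "chrom": chrom if chrom is not None else ["1"] * p,
            "pos": pos if pos is not None else (np.arange(p) + 1) * 10_000,
            "a1": "A",
            "a2": "B",
        }
    )
    return GenotypeMatrix(dosages=dosages, snp_meta=meta, sample_ids=sample_ids)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_genotypes(rng) -> GenotypeMatrix:
    """60 samples x 12 SNPs in HWE, no missingness."""
    freqs = rng.uniform(0.1, 0.5, size=12)
    dosages = rng.binomial(2, freqs, size=(60, 12)).astype(np.int8)
    return make_matrix(dosages)
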