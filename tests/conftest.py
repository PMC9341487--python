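import numpy as np
import pandas as pd
import pytest

from popchar.genotype_io import GenotypePanel


def make_panel(
    dosages,
    positions=None,
    chrom=None,
    populations=None,
    spacing_bp=100_000,
):
    """Small GenotypePanel from a dosage matrix (rows = individuals)."""
    d = np.asarray(dosages, dtype=np.int8)
    n, m = d.shape
    if positions is None:
        positions = (np.arange(m) + 1) * spacing_bp
    positions = np.asarray(positions)
    if chrom is None:
        chrom = np.ones(m, dtype=int)
    chrom = np.asarray(chrom)
    variants = pd.DataFrame(
        {
            "snp_id": [f"snp{j}" for j in range(m)],
            "chrom": chrom,
            "pos_bp": positions,
            "allele_a": "A",
            "allele_b": "B",
        }
    )
    if populations is None:
        populations = ["POP"] * n
    samples = pd.DataFrame({"iid": [f"ind{i}" for i in range(n)], "population": populations})
    return GenotypePanel(variants, samples, d)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_panel(rng, n=20, m=50, maf_low=0.1, missing_rate=0.0, spacing_bp=100_000):
    """Random HWE panel with allele frequencies bounded away from 0/1."""
    p = rng.uniform(maf_low, 1 - maf_low, size=m)
    d = (rng.random((n, m)) < p).astype(np.int8) + (rng.random((n, m)) < p).astype(np.int8)
    if missing_rate:
        d[rng.random((n, m)) < missing_rate] = -1
    # guarantee every column is polymorphic
    for j in range(m):
        col = d[:, j][d[:, j] != -1]
        if col.size == 0 or (col == col[0]).all():
            d[0, j] = 1
    return make_panel(d, spacing_bp=spacing_bp)
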