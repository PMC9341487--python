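import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from conftest import make_panel, random_panel
from popchar.genotype_io import (
    MISSING,
    FormatError,
    GenotypePanel,
    QCParams,
    allele_frequencies,
    hwe_exact_pvalue,
    intersect_panels,
    maf_spectrum,
    qc_filter,
    read_panel,
    write_panel,
)


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("fmt", ["ped", "bed"])
def test_round_trip_preserves_dosages_positions_ids(tmp_path, rng, fmt):
    panel = random_panel(rng, n=100, m=500, maf_low=0.15, missing_rate=0.05)
    # guarantee both alleles observed at every SNP (PED has no allele metadata)
    keep = [(panel.dosages[:, j] != 2).any() and (panel.dosages[:, j] > 0).any()
            for j in range(panel.n_snps)]
    panel = panel.subset_variants(np.nonzero(keep)[0])
    write_panel(panel, tmp_path / "x", format=fmt)
    back = read_panel(tmp_path / "x", format=fmt)
    assert np.array_equal(back.dosages, panel.dosages)
    assert back.variants["pos_bp"].tolist() == panel.variants["pos_bp"].tolist()
    assert back.samples["iid"].tolist() == panel.samples["iid"].tolist()


def test_bed_missing_code_decoded_by_hand(tmp_path):
    # one SNP, one individual, 2-bit code 0b01 = missing (PLINK SNP-major BED)
    (tmp_path / "m.bim").write_text("1\tsnp1\t0\t1000\tA\tB\n")
    (tmp_path / "m.fam").write_text("P\tind1\t0\t0\t0\t-9\n")
    (tmp_path / "m.bed").write_bytes(bytes([0x6C, 0x1B, 0x01, 0b01]))
    panel = read_panel(tmp_path / "m", format="bed")
    assert panel.dosages[0, 0] == MISSING


def test_bed_codes_cover_all_dosages(tmp_path):
    # 4 individuals in one byte: codes 00, 01, 10, 11 -> 0, missing, 1, 2
    (tmp_path / "m.bim").write_text("1\tsnp1\t0\t1000\tA\tB\n")
    (tmp_path / "m.fam").write_text(
        "".join(f"P\tind{i}\t0\t0\t0\t-9\n" for i in range(4))
    )
    (tmp_path / "m.bed").write_bytes(bytes([0x6C, 0x1B, 0x01, 0b11100100]))
    panel = read_panel(tmp_path / "m", format="bed")
    assert panel.dosages[:, 0].tolist() == [0, MISSING, 1, 2]


def test_non_autosome_snp_removed_on_read(tmp_path):
    (tmp_path / "m.bim").write_text(
        "1\tsnp1\t0\t1000\tA\tB\nX\tsnpx\t0\t500\tA\tB\n2\tsnp2\t0\t2000\tA\tB\n"
    )
    (tmp_path / "m.fam").write_text("P\tind1\t0\t0\t0\t-9\n")
    (tmp_path / "m.bed").write_bytes(bytes([0x6C, 0x1B, 0x01, 0b11, 0b11, 0b11]))
    with pytest.warns(UserWarning, match="non-autosomal"):
        panel = read_panel(tmp_path / "m", format="bed")
    assert panel.n_snps == 2
    assert panel.variants["snp_id"].tolist() == ["snp1", "snp2"]


def test_unknown_chromosome_code_rejected(tmp_path):
    (tmp_path / "m.bim").write_text("chr_weird\tsnp1\t0\t1000\tA\tB\n")
    (tmp_path / "m.fam").write_text("P\tind1\t0\t0\t0\t-9\n")
    (tmp_path / "m.bed").write_bytes(bytes([0x6C, 0x1B, 0x01, 0b11]))
    with pytest.raises(FormatError):
        read_panel(tmp_path / "m", format="bed")


def test_write_empty_panel_rejected(tmp_path):
    panel = make_panel(np.zeros((1, 1)))
    empty = GenotypePanel(panel.variants, panel.samples.iloc[:0], panel.dosages[:0])
    with pytest.raises(ValueError):
        write_panel(empty, tmp_path / "e", format="ped")


def test_ped_line_writes_homozygous_allele_b(tmp_path):
    panel = make_panel([[2]])
    write_panel(panel, tmp_path / "one", format="ped")
    line = (tmp_path / "one.ped").read_text().strip()
    assert line.split()[-2:] == ["B", "B"]


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

def test_allele_frequency_basic_missing_and_monomorphic():
    panel = make_panel(np.array([[0, 2, 0], [1, 2, 0], [2, MISSING, 0]]))
    p = allele_frequencies(panel)
    assert p[0] == pytest.approx(0.5)
    assert p[1] == pytest.approx(1.0)  # missing call excluded
    assert p[2] == 0.0


def test_allele_frequency_all_missing_names_snp():
    panel = make_panel(np.array([[MISSING], [MISSING]]))
    with pytest.raises(ValueError, match="snp0"):
        allele_frequencies(panel)


def test_allele_frequencies_invariant_to_individual_order(rng):
    panel = random_panel(rng, n=30, m=40, missing_rate=0.1)
    perm = rng.permutation(30)
    shuffled = GenotypePanel(
        panel.variants, panel.samples.iloc[perm], panel.dosages[perm]
    )
    assert np.allclose(allele_frequencies(panel), allele_frequencies(shuffled))


# ---------------------------------------------------------------------------
# HWE exact test
# ---------------------------------------------------------------------------

def test_hwe_monomorphic_is_one():
    assert hwe_exact_pvalue(0, 0, 50) == 1.0


def test_hwe_matches_enumeration_oracle_balanced():
    assert hwe_exact_pvalue(25, 50, 25) == pytest.approx(
        oracles.hwe_enumeration_pvalue(25, 50, 25), rel=1e-10
    )


def test_hwe_all_homozygote_extreme_is_tiny():
    assert hwe_exact_pvalue(50, 0, 50) < 1e-6


@settings(max_examples=60, deadline=None)
@given(
    st.integers(min_value=0, max_value=25),
    st.integers(min_value=0, max_value=25),
    st.integers(min_value=0, max_value=25),
)
def test_hwe_equals_oracle_and_in_unit_interval(naa, nab, nbb):
    if naa + nab + nbb == 0:
        return
    p = hwe_exact_pvalue(naa, nab, nbb)
    assert 0.0 < p <= 1.0
    assert p == pytest.approx(oracles.hwe_enumeration_pvalue(naa, nab, nbb), rel=1e-9)


# ---------------------------------------------------------------------------
# QC filter
# ---------------------------------------------------------------------------

def test_qc_call_rate_removal():
    d = np.ones((10, 2), dtype=np.int8)
    d[:2, 0] = MISSING  # 8/10 calls < 0.90
    panel = make_panel(d)
    out, report = qc_filter(panel, QCParams(apply_maf_hwe=False))
    assert report.removed["call_rate"] == 1
    assert out.variants["snp_id"].tolist() == ["snp1"]


def test_qc_duplicate_position_keeps_first():
    panel = make_panel(np.array([[0, 2, 1], [1, 1, 1]]), positions=[100, 100, 200])
    out, report = qc_filter(panel, QCParams(apply_maf_hwe=False))
    assert report.removed["duplicate_position"] == 1
    assert out.variants["snp_id"].tolist() == ["snp0", "snp2"]


def test_qc_maf_retention_matches_hand_enumeration():
    # 10 SNPs x 10 individuals with dosage-b counts giving p = k/20
    counts = [0, 1, 2, 3, 5, 8, 10, 15, 19, 20]  # MAF: 0,.05,.1,.15,.25,.4,.5,.25,.05,0
    d = np.zeros((10, 10), dtype=np.int8)
    for j, k in enumerate(counts):
        d[: k // 2, j] = 2
        if k % 2:
            d[k // 2, j] = 1
    panel = make_panel(d)
    out, report = qc_filter(panel, QCParams(min_maf=0.05, hwe_p_floor=0.0))
    # retained: MAF >= 0.05 -> columns 1..8 (p in .05..0.95)
    assert out.variants["snp_id"].tolist() == [f"snp{j}" for j in range(1, 9)]
    assert report.removed["maf"] == 2


def test_qc_idempotent(rng):
    panel = random_panel(rng, n=40, m=60, maf_low=0.02, missing_rate=0.08)
    once, _ = qc_filter(panel)
    twice, report = qc_filter(once)
    assert sum(report.removed.values()) == 0
    assert np.array_equal(once.dosages, twice.dosages)


def test_qc_all_removed_raises():
    panel = make_panel(np.full((10, 1), MISSING, dtype=np.int8))
    panel.dosages[0, 0] = 1  # 10% call rate
    with pytest.raises(ValueError, match="every SNP"):
        qc_filter(panel)


# ---------------------------------------------------------------------------
# MAF spectrum
# ---------------------------------------------------------------------------

def test_maf_spectrum_edges_and_top_bin():
    # p = 0.5 -> (0.45, 0.50]; p = 0.05 -> (0, 0.05] (closed right edge)
    d = np.zeros((10, 2), dtype=np.int8)
    d[:5, 0] = 2  # p = 0.5
    d[0, 1] = 1  # p = 0.05
    spec = maf_spectrum(make_panel(d))
    assert spec.loc[spec["bin"] == "(0.45,0.50]", "count"].item() == 1
    assert spec.loc[spec["bin"] == "(0.00,0.05]", "count"].item() == 1


def test_maf_spectrum_proportions_sum_to_one_uniform(rng):
    n_snps = 1000
    maf = rng.uniform(0, 0.5, size=n_snps)
    n = 1000  # large sample so realized MAF tracks the target closely
    d = (rng.random((n, n_snps)) < maf).astype(np.int8) + (
        rng.random((n, n_snps)) < maf
    ).astype(np.int8)
    spec = maf_spectrum(make_panel(d))
    poly = spec.loc[spec["bin"] != "monomorphic"]
    assert poly["proportion"].sum() == pytest.approx(1.0)
    sd = np.sqrt(0.1 * 0.9 / n_snps)
    assert (np.abs(poly["proportion"] - 0.10) < 3 * sd + 0.02).all()


# ---------------------------------------------------------------------------
# panel intersection
# ---------------------------------------------------------------------------

def test_intersect_identical_panels_unchanged(rng):
    panel = random_panel(rng, n=10, m=20)
    a, b = intersect_panels(panel, panel.copy())
    assert np.array_equal(a.dosages, panel.dosages)
    assert np.array_equal(b.dosages, panel.dosages)


def test_intersect_complements_swapped_alleles():
    a = make_panel(np.array([[0, 1, 2]]))
    b = make_panel(np.array([[2, 1, MISSING]]))
    b.variants.loc[0, ["allele_a", "allele_b"]] = ["B", "A"]  # swapped at SNP 0
    ia, ib = intersect_panels(a, b)
    assert ib.dosages[0].tolist() == [0, 1, MISSING]
    assert ib.variants.loc[0, "allele_b"] == "B"


def test_intersect_keeps_shared_subset_in_order():
    a = make_panel(np.zeros((2, 5), dtype=np.int8), positions=[10, 20, 30, 40, 50])
    b = make_panel(np.ones((3, 3), dtype=np.int8), positions=[20, 40, 50])
    ia, ib = intersect_panels(a, b)
    assert ia.variants["pos_bp"].tolist() == [20, 40, 50]
    assert ib.variants["pos_bp"].tolist() == [20, 40, 50]
    assert ia.n_individuals == 2 and ib.n_individuals == 3


def test_intersect_empty_errors():
    a = make_panel(np.zeros((1, 2), dtype=np.int8), positions=[10, 20])
    b = make_panel(np.zeros((1, 2), dtype=np.int8), positions=[30, 40])
    with pytest.raises(ValueError, match="share no"):
        intersect_panels(a, b)
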