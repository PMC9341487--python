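import numpy as np
import pandas as pd
import pytest

import oracles
from conftest import make_panel
from popchar.genotype_io import MISSING
from popchar.roh_her import (
    HERParams,
    ROHParams,
    call_islands,
    classify_segments,
    detect_her,
    detect_roh,
    f_roh,
    snp_covered_genome_bp,
)


def het_background_panel(rng, n=4, m=300, spacing=30_000):
    """Mostly heterozygous individuals (no spontaneous ROH)."""
    d = np.ones((n, m), dtype=np.int8)
    noise = rng.random((n, m))
    d[noise < 0.15] = 0
    d[noise > 0.90] = 2
    return make_panel(d, spacing_bp=spacing)


def hom_background_panel(rng, n=4, m=300, spacing=30_000):
    """Mostly homozygous individuals (no spontaneous HER)."""
    d = np.zeros((n, m), dtype=np.int8)
    noise = rng.random((n, m))
    d[noise < 0.3] = 2
    d[(noise >= 0.3) & (noise < 0.45)] = 1
    return make_panel(d, spacing_bp=spacing)


# ---------------------------------------------------------------------------
# ROH
# ---------------------------------------------------------------------------

def test_planted_tract_yields_single_roh_with_tight_bounds(rng):
    panel = het_background_panel(rng)
    pos = panel.variants["pos_bp"].to_numpy()
    lo, hi = 100, 200  # 100 SNPs over ~3 Mb
    panel.dosages[0, lo: hi + 1] = 2
    segs = detect_roh(panel, ROHParams())
    mine = segs.loc[segs["iid"] == "ind0"]
    assert len(mine) == 1
    seg = mine.iloc[0]
    w_bp = 50 * 30_000
    assert abs(seg.start_bp - pos[lo]) <= w_bp
    assert abs(seg.end_bp - pos[hi]) <= w_bp
    assert segs.loc[segs["iid"] != "ind0"].empty


def test_all_heterozygous_individual_has_no_roh():
    panel = make_panel(np.ones((1, 200), dtype=np.int8), spacing_bp=30_000)
    assert detect_roh(panel, ROHParams()).empty


def test_short_sparse_tract_rejected_by_thresholds(rng):
    # 20 homozygous SNPs spanning 400 kb: fails min_snps (30) and min_length
    panel = het_background_panel(rng, m=300, spacing=20_000)
    panel.dosages[0, 100:120] = 0
    segs = detect_roh(panel, ROHParams())
    assert segs.loc[segs["iid"] == "ind0"].empty


def test_unsorted_positions_rejected(rng):
    panel = het_background_panel(rng, m=60)
    panel.variants.loc[5, "pos_bp"] = panel.variants.loc[4, "pos_bp"]
    with pytest.raises(ValueError, match="not strictly increasing"):
        detect_roh(panel, ROHParams())


@pytest.mark.parametrize("seed", range(6))
def test_detect_roh_matches_bruteforce_window_oracle(seed):
    rng = np.random.default_rng(7000 + seed)
    m = 200
    # genotype mix with long homozygous stretches to trigger calls
    d = np.ones((3, m), dtype=np.int8)
    for i in range(3):
        x = 0
        while x < m:
            run = int(rng.integers(10, 80))
            kind = rng.choice([0, 1, 2, MISSING], p=[0.35, 0.3, 0.3, 0.05])
            d[i, x: x + run] = kind
            x += run
    pos = np.sort(rng.choice(np.arange(1, 8_000_000), size=m, replace=False))
    panel = make_panel(d, positions=pos)
    params = ROHParams()
    segs = detect_roh(panel, params)
    for i in range(3):
        expected = oracles.naive_roh(d[i], pos, params)
        got = [
            (r.start_bp, r.end_bp, r.n_snps)
            for r in segs.loc[segs["iid"] == f"ind{i}"].itertuples()
        ]
        assert got == expected, f"individual {i}"


# ---------------------------------------------------------------------------
# HER
# ---------------------------------------------------------------------------

def test_planted_het_tract_yields_her(rng):
    panel = hom_background_panel(rng)
    pos = panel.variants["pos_bp"].to_numpy()
    lo, hi = 100, 125  # 26 SNPs over 750 kb
    panel.dosages[1, lo: hi + 1] = 1
    segs = detect_her(panel, HERParams())
    mine = segs.loc[segs["iid"] == "ind1"]
    assert len(mine) >= 1
    seg = mine.iloc[0]
    assert seg.start_bp <= pos[lo] and seg.end_bp >= pos[hi] - 100_000


def test_fully_homozygous_individual_has_no_her():
    panel = make_panel(np.zeros((1, 200), dtype=np.int8), spacing_bp=30_000)
    assert detect_her(panel, HERParams()).empty


def test_her_run_split_by_homozygous_interruptions():
    # hand trace: 30 hets, 3 homozygous, 30 hets; max_homozygous = 2 forces a
    # split at the third consecutive homozygous call
    g = np.concatenate([np.ones(30), np.zeros(3), np.ones(30)]).astype(np.int8)
    panel = make_panel(g.reshape(1, -1), spacing_bp=30_000)
    params = HERParams(min_snps=20, min_length_bp=500_000)
    segs = detect_her(panel, params)
    assert len(segs) == 2
    pos = panel.variants["pos_bp"].to_numpy()
    first, second = segs.iloc[0], segs.iloc[1]
    # first run: hets 0..29 plus 2 allowed homs, closed at the 3rd hom,
    # trimmed back to the last het (index 29)
    assert first.start_bp == pos[0] and first.end_bp == pos[29]
    # scan restarts after the violating SNP -> second run starts at SNP 33
    assert second.start_bp == pos[33] and second.end_bp == pos[62]


def test_her_audit_max_homozygous_never_exceeded(rng):
    d = rng.choice([0, 1, 2, MISSING], p=[0.3, 0.4, 0.25, 0.05], size=(5, 400)).astype(np.int8)
    panel = make_panel(d, spacing_bp=30_000)
    params = HERParams(min_snps=10, min_length_bp=200_000)
    segs = detect_her(panel, params)
    pos = panel.variants["pos_bp"].to_numpy()
    for r in segs.itertuples():
        i = int(r.iid[3:])
        sel = (pos >= r.start_bp) & (pos <= r.end_bp)
        g = d[i, sel]
        assert ((g == 0) | (g == 2)).sum() <= params.max_homozygous
        assert (g == MISSING).sum() <= params.max_missing


# ---------------------------------------------------------------------------
# classification & F_ROH
# ---------------------------------------------------------------------------

def test_classify_three_lengths_and_boundary():
    segs = pd.DataFrame(
        {"length_bp": [1_900_000, 3_000_000, 20_000_000, 4_000_000]}
    )
    out = classify_segments(segs, "ROH")
    base = out.loc[~out["aggregate"]].set_index("class")
    assert base.loc["<2Mb", "count"] == 1
    assert base.loc["2-4Mb", "count"] == 1
    assert base.loc[">16Mb", "count"] == 1
    assert base.loc["4-8Mb", "count"] == 1  # 4.0 Mb -> left-closed 4-8 class
    assert base["pct"].sum() == pytest.approx(100.0)


def test_classify_empty_input_all_zero():
    out = classify_segments(pd.DataFrame(columns=["length_bp"]), "HER")
    assert (out["count"] == 0).all()


def test_f_roh_simple_fraction_and_no_segments():
    panel = make_panel(
        np.ones((2, 101), dtype=np.int8),
        positions=np.linspace(1, 100_000_001, 101).astype(int),
    )
    assert snp_covered_genome_bp(panel) == 100_000_000
    segs = pd.DataFrame(
        [{"iid": "ind0", "chrom": 1, "start_bp": 1, "end_bp": 10_000_001,
          "n_snps": 11, "length_bp": 10_000_000, "kind": "ROH"}]
    )
    table = f_roh(segs, panel)
    assert table.loc["ind0", "F_ROH"] == pytest.approx(0.1)
    assert table.loc["ind1", "F_ROH"] == 0.0


def test_f_roh_class_additivity_exact(rng):
    panel = make_panel(np.ones((5, 100), dtype=np.int8), spacing_bp=1_000_000)
    rows = []
    for i in range(5):
        for _ in range(6):
            start = int(rng.integers(1, 60)) * 1_000_000
            length = int(rng.integers(1, 30)) * 1_000_000 + 500_000
            rows.append({"iid": f"ind{i}", "chrom": 1, "start_bp": start,
                         "end_bp": start + length, "n_snps": 10,
                         "length_bp": length, "kind": "ROH"})
    table = f_roh(pd.DataFrame(rows), panel)
    class_sum = table[["<2Mb", "2-4Mb", "4-8Mb", "8-16Mb", ">16Mb"]].sum(axis=1)
    assert np.allclose(class_sum, table["F_ROH"], atol=1e-12)
    agg_sum = table[["<8Mb", ">8Mb"]].sum(axis=1)
    assert np.allclose(agg_sum, table["F_ROH"], atol=1e-12)


# ---------------------------------------------------------------------------
# islands
# ---------------------------------------------------------------------------

def test_islands_from_shared_plant_threshold_behavior():
    panel = make_panel(np.ones((10, 100), dtype=np.int8), spacing_bp=30_000)
    pos = panel.variants["pos_bp"].to_numpy()
    segs = pd.DataFrame(
        [{"iid": f"ind{i}", "chrom": 1, "start_bp": pos[20], "end_bp": pos[60],
          "n_snps": 41, "length_bp": pos[60] - pos[20], "kind": "ROH"}
         for i in range(4)]  # 4 of 10 individuals share the region
    )
    isl = call_islands(segs, panel, min_incidence=0.36)
    assert len(isl) == 1
    assert isl.iloc[0].start_bp == pos[20] and isl.iloc[0].end_bp == pos[60]
    assert isl.iloc[0].incidence == pytest.approx(0.4)
    assert call_islands(segs, panel, min_incidence=0.5).empty


def test_islands_min_incidence_zero_degenerate():
    panel = make_panel(np.ones((2, 50), dtype=np.int8), spacing_bp=30_000)
    pos = panel.variants["pos_bp"].to_numpy()
    segs = pd.DataFrame(
        [
            {"iid": "ind0", "chrom": 1, "start_bp": pos[5], "end_bp": pos[10],
             "n_snps": 6, "length_bp": pos[10] - pos[5], "kind": "ROH"},
            {"iid": "ind1", "chrom": 1, "start_bp": pos[30], "end_bp": pos[40],
             "n_snps": 11, "length_bp": pos[40] - pos[30], "kind": "ROH"},
        ]
    )
    isl = call_islands(segs, panel, min_incidence=0.0)
    assert len(isl) == 2  # one island per covered stretch


# ---------------------------------------------------------------------------
# planted-truth sweep: thresholds met -> detected; any violated -> not
# ---------------------------------------------------------------------------

def test_planted_recovery_sweep(rng):
    spacing = 30_000
    detected = 0
    n_plants = 30
    for k in range(n_plants):
        panel = het_background_panel(rng, n=1, m=400, spacing=spacing)
        lo = int(rng.integers(60, 200))
        # at least one full window of SNPs: shorter tracts flanked by dense
        # heterozygosity are undetectable under sliding-window semantics
        n_snps = int(rng.integers(55, 120))
        panel.dosages[0, lo: lo + n_snps] = rng.choice([0, 2], size=n_snps)
        segs = detect_roh(panel, ROHParams())
        pos = panel.variants["pos_bp"].to_numpy()
        span = (pos[lo], pos[lo + n_snps - 1])
        hits = segs.loc[
            (segs["start_bp"] < span[1]) & (segs["end_bp"] > span[0])
        ]
        w_bp = 50 * spacing  # boundary slack: one window per side
        if len(hits) and all(
            min(h.end_bp, span[1]) - max(h.start_bp, span[0])
            >= 0.9 * (span[1] - span[0])
            and h.start_bp >= span[0] - w_bp
            and h.end_bp <= span[1] + w_bp
            for h in hits.itertuples()
        ):
            detected += 1
    assert detected == n_plants

    # violating a single threshold -> never detected
    for k in range(10):
        panel = het_background_panel(rng, n=1, m=400, spacing=spacing)
        lo = int(rng.integers(60, 200))
        panel.dosages[0, lo: lo + 25] = 0  # 25 < min_snps, 720 kb
        segs = detect_roh(panel, ROHParams())
        assert segs.empty
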