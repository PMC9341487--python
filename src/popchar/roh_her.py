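"""Runs of homozygosity (ROH), heterozygosity-enriched regions (HER), length
classification, F_ROH and incidence-based island calling.

ROH detection follows the PLINK ``--homozyg`` scanning scheme: a fixed-size
SNP window slides along each individual's chromosome; a window passes if it
contains at most ``window_max_het`` heterozygous and ``window_max_missing``
missing calls; a SNP is "in run" when the fraction of passing windows among
all windows overlapping it reaches ``window_hit_threshold``.  Maximal in-run
stretches become candidate segments, split at inter-SNP gaps above
``max_gap_bp`` and then filtered on SNP count, physical length and marker
density.

HER detection uses the consecutive-SNP scan (detectRUNS-style): runs grow
left to right while the counts of homozygous and missing calls stay within
their allowances; runs are trimmed to heterozygous end-points.

Segment length is end_bp − start_bp (not +1) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypePanel

SEGMENT_COLUMNS = ["iid", "chrom", "start_bp", "end_bp", "n_snps", "length_bp", "kind"]

ROH_CLASSES_MB = [(0, 2), (2, 4), (4, 8), (8, 16), (16, np.inf)]
ROH_AGGREGATES_MB = [(0, 8), (8, np.inf)]
HER_CLASSES_MB = [(0.5, 1.0), (1.0, 1.5), (1.5, 2.0), (2.0, np.inf)]


@dataclass
class ROHParams:
    window_snps: int = 50
    window_max_het: int = 1
    window_max_missing: int = 1
    window_hit_threshold: float = 0.05
    max_gap_bp: int = 1_000_000
    min_length_bp: int = 500_000
    min_snps: int = 30
    min_density_bp_per_snp: int = 50_000

    def __post_init__(self) -> None:
        for k, v in asdict(self).items():
            if v <= 0:
                raise ValueError(f"ROH parameter {k} must be positive")


@dataclass
class HERParams:
    min_snps: int = 20
    min_length_bp: int = 500_000
    max_homozygous: int = 2
    max_missing: int = 1
    max_gap_bp: int = 1_000_000


def _check_sorted(panel: GenotypePanel) -> None:
    v = panel.variants
    for c in v["chrom"].unique():
        pos = v.loc[v["chrom"] == c, "pos_bp"].to_numpy()
        if not (np.diff(pos) > 0).all():
            raise ValueError(f"positions on chromosome {c} are not strictly increasing")


def _segment_frame(rows: list[dict]) -> pd.DataFrame:
    if not rows:
        return pd.DataFrame(columns=SEGMENT_COLUMNS)
    return pd.DataFrame(rows)[SEGMENT_COLUMNS]


def _emit(rows, iid, chrom, pos, idx_start, idx_end, kind) -> None:
    start, end = int(pos[idx_start]), int(pos[idx_end])
    rows.append(
        {
            "iid": iid,
            "chrom": int(chrom),
            "start_bp": start,
            "end_bp": end,
            "n_snps": int(idx_end - idx_start + 1),
            "length_bp": end - start,
            "kind": kind,
        }
    )


def _in_run_snps(g: np.ndarray, params: ROHParams) -> np.ndarray:
    """Boolean in-run flag per SNP from the sliding-window vote."""
    n = len(g)
    w = params.window_snps
    if n < w:
        return np.zeros(n, dtype=bool)
    het = (g == 1).astype(int)
    mis = (g == MISSING).astype(int)
    kern = np.ones(w)
    het_w = np.convolve(het, kern, mode="valid")  # length n - w + 1
    mis_w = np.convolve(mis, kern, mode="valid")
    passing = (het_w <= params.window_max_het) & (mis_w <= params.window_max_missing)
    # windows overlapping SNP k: indices max(0, k-w+1) .. min(k, nw-1)
    nw = n - w + 1
    cpass = np.concatenate([[0], np.cumsum(passing)])
    k = np.arange(n)
    lo = np.maximum(0, k - w + 1)
    hi = np.minimum(k, nw - 1)
    n_overlap = hi - lo + 1
    n_pass = cpass[hi + 1] - cpass[lo]
    return n_pass / n_overlap >= params.window_hit_threshold


def _candidate_runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end] index stretches where flags is True."""
    if not flags.any():
        return []
    d = np.diff(flags.astype(int))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0])
    if flags[0]:
        starts = [0] + starts
    if flags[-1]:
        ends = ends + [len(flags) - 1]
    return list(zip(starts, ends))


def detect_roh(panel: GenotypePanel, params: ROHParams | None = None) -> pd.DataFrame:
    """Sliding-window ROH calls for every individual (see module docstring)."""
    params = params or ROHParams()
    _check_sorted(panel)
    v = panel.variants
    chrom_arr = v["chrom"].to_numpy()
    pos_arr = v["pos_bp"].to_numpy()
    rows: list[dict] = []
    for i, iid in enumerate(panel.samples["iid"]):
        for c in np.unique(chrom_arr):
            idx = np.nonzero(chrom_arr == c)[0]
            g = panel.dosages[i, idx]
            pos = pos_arr[idx]
            flags = _in_run_snps(g, params)
            for s, e in _candidate_runs(flags):
                # split at large gaps
                gaps = np.diff(pos[s: e + 1])
                cut_after = np.nonzero(gaps > params.max_gap_bp)[0]
                bounds = [s] + [s + cb + 1 for cb in cut_after] + [e + 1]
                for bs, be in zip(bounds[:-1], bounds[1:]):
                    be -= 1
                    n_snps = be - bs + 1
                    length = pos[be] - pos[bs]
                    if n_snps < params.min_snps or length < params.min_length_bp:
                        continue
                    if n_snps and length / n_snps > params.min_density_bp_per_snp:
                        continue
                    _emit(rows, iid, c, pos, bs, be, "ROH")
    return _segment_frame(rows)


def detect_her(panel: GenotypePanel, params: HERParams | None = None) -> pd.DataFrame:
    """Consecutive-SNP HER calls (greedy left-to-right scan).

    A run starts at a heterozygous SNP and grows while homozygous calls
    ≤ max_homozygous, missing calls ≤ max_missing and inter-SNP gaps
    ≤ max_gap_bp; on violation the run closes (trimmed to its last
    heterozygous SNP) and scanning restarts after the violating SNP.
    """
    params = params or HERParams()
    _check_sorted(panel)
    v = panel.variants
    chrom_arr = v["chrom"].to_numpy()
    pos_arr = v["pos_bp"].to_numpy()
    rows: list[dict] = []
    for i, iid in enumerate(panel.samples["iid"]):
        for c in np.unique(chrom_arr):
            idx = np.nonzero(chrom_arr == c)[0]
            g = panel.dosages[i, idx]
            pos = pos_arr[idx]
            n = len(idx)

            def close(start: int, last_het: int) -> None:
                if start is None or last_het is None or last_het <= start:
                    return
                n_snps = last_het - start + 1
                length = pos[last_het] - pos[start]
                if n_snps >= params.min_snps and length >= params.min_length_bp:
                    _emit(rows, iid, c, pos, start, last_het, "HER")

            start = None
            last_het = None
            n_hom = n_mis = 0
            for k in range(n):
                if start is not None and pos[k] - pos[k - 1] > params.max_gap_bp:
                    close(start, last_het)
                    start, last_het, n_hom, n_mis = None, None, 0, 0
                call = g[k]
                if start is None:
                    if call == 1:
                        start, last_het, n_hom, n_mis = k, k, 0, 0
                    continue
                if call == 1:
                    last_het = k
                elif call == MISSING:
                    if n_mis + 1 > params.max_missing:
                        close(start, last_het)
                        start, last_het, n_hom, n_mis = None, None, 0, 0
                    else:
                        n_mis += 1
                else:  # homozygous
                    if n_hom + 1 > params.max_homozygous:
                        close(start, last_het)
                        start, last_het, n_hom, n_mis = None, None, 0, 0
                    else:
                        n_hom += 1
            close(start, last_het)
    return _segment_frame(rows)


def classify_segments(segments: pd.DataFrame, kind: str = "ROH") -> pd.DataFrame:
    """Counts and percentages per length class (left-closed, right-open bins).

    ROH classes <2 / 2–4 / 4–8 / 8–16 / >16 Mb (plus <8 and >8 Mb aggregate
    rows, flagged ``aggregate``); HER classes 0.5–1 / 1–1.5 / 1.5–2 / >2 Mb.
    Percentages sum to 100 over the disjoint (non-aggregate) classes.
    """
    classes = ROH_CLASSES_MB if kind.upper() == "ROH" else HER_CLASSES_MB
    lengths = segments["length_bp"].to_numpy() / 1e6 if len(segments) else np.empty(0)
    total = len(lengths)
    rows = []
    for lo, hi in classes:
        n = int(((lengths >= lo) & (lengths < hi)).sum())
        rows.append(
            {
                "class": _class_label(lo, hi),
                "count": n,
                "pct": 100.0 * n / total if total else 0.0,
                "aggregate": False,
            }
        )
    if kind.upper() == "ROH":
        for lo, hi in ROH_AGGREGATES_MB:
            n = int(((lengths >= lo) & (lengths < hi)).sum())
            rows.append(
                {
                    "class": _class_label(lo, hi),
                    "count": n,
                    "pct": 100.0 * n / total if total else 0.0,
                    "aggregate": True,
                }
            )
    return pd.DataFrame(rows)


def _class_label(lo: float, hi: float) -> str:
    if lo == 0:
        return f"<{hi:g}Mb"
    if np.isinf(hi):
        return f">{lo:g}Mb"
    return f"{lo:g}-{hi:g}Mb"


def snp_covered_genome_bp(panel: GenotypePanel) -> int:
    """Σ over autosomes of (last SNP bp − first SNP bp): the F_ROH denominator."""
    v = panel.variants
    g = v.groupby("chrom")["pos_bp"]
    return int((g.max() - g.min()).sum())


def f_roh(segments: pd.DataFrame, panel: GenotypePanel) -> pd.DataFrame:
    """Per-individual F_ROH (total and per length class).

    F_ROH = Σ segment lengths / SNP-covered autosomal genome length; the
    class columns sum to the total exactly.
    """
    denom = snp_covered_genome_bp(panel)
    iids = list(panel.samples["iid"])
    cols = {_class_label(lo, hi): (lo, hi) for lo, hi in ROH_CLASSES_MB}
    agg = {_class_label(lo, hi): (lo, hi) for lo, hi in ROH_AGGREGATES_MB}
    out = pd.DataFrame(0.0, index=iids, columns=["F_ROH"] + list(cols) + list(agg))
    if len(segments):
        for iid, sub in segments.groupby("iid"):
            if iid not in out.index:
                continue
            L = sub["length_bp"].to_numpy()
            out.loc[iid, "F_ROH"] = L.sum() / denom
            mb = L / 1e6
            for label, (lo, hi) in {**cols, **agg}.items():
                out.loc[iid, label] = L[(mb >= lo) & (mb < hi)].sum() / denom
    out.index.name = "iid"
    return out


def call_islands(
    segments: pd.DataFrame, panel: GenotypePanel, min_incidence: float
) -> pd.DataFrame:
    """Incidence-based islands: maximal stretches of SNPs covered by segments
    in at least ``min_incidence`` of the individuals.

    Island boundaries snap to the first/last qualifying SNP; the reported
    incidence is the maximum per-SNP incidence inside the island.
    """
    v = panel.variants
    n_ind = panel.n_individuals
    rows = []
    for c in v["chrom"].unique():
        idx = np.nonzero((v["chrom"] == c).to_numpy())[0]
        pos = v["pos_bp"].to_numpy()[idx]
        cover = np.zeros(len(idx))
        subs = segments.loc[segments["chrom"] == c] if len(segments) else segments
        for _, seg in subs.iterrows():
            a = np.searchsorted(pos, seg["start_bp"], side="left")
            b = np.searchsorted(pos, seg["end_bp"], side="right")
            cover[a:b] += 1
        incidence = cover / n_ind
        qualify = incidence >= min_incidence if min_incidence > 0 else cover > 0
        for s, e in _candidate_runs(qualify):
            rows.append(
                {
                    "chrom": int(c),
                    "start_bp": int(pos[s]),
                    "end_bp": int(pos[e]),
                    "length_bp": int(pos[e] - pos[s]),
                    "n_snps": int(e - s + 1),
                    "incidence": float(incidence[s: e + 1].max()),
                }
            )
    return pd.DataFrame(
        rows, columns=["chrom", "start_bp", "end_bp", "length_bp", "n_snps", "incidence"]
    )
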