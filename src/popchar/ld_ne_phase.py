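"""Two-locus linkage disequilibrium, binned LD decay, LD-based effective
population size, and cross-population consistency of gametic phase (CGP).

Haplotype frequencies are estimated from unphased genotypes by EM over the
double-heterozygote ambiguity (the estimator underlying PLINK's r²).  For a
pair of loci with allele_b frequencies p_a, p_b and haplotype frequency
p(ab):  D = p(ab) − p(a)p(b)  and  r² = D² / (p_a(1−p_a) p_b(1−p_b)).
The signed-r statistic sign(D)·sqrt(r²) is what transfers (or fails to)
across populations: CGP is its per-distance-bin Pearson correlation between
two panels over the same SNP pairs.

Ne is inverted from binned mean r² via the Sved relation
E[r²] = 1/(α + 4 Ne c):  Ne(T) = (1/(4c)) (1/r² − α), with c the inter-marker
distance in Morgans (f(c) = c) and T = 1/(2c) generations ago.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypePanel, intersect_panels

EM_TOL = 1e-10
EM_MAX_ITER = 200


def _default_edges() -> np.ndarray:
    """10–100 kb in 10-kb steps, then 100–1,000 kb in 100-kb steps (bp)."""
    return np.concatenate(
        [[0], np.arange(10_000, 100_001, 10_000), np.arange(200_000, 1_000_001, 100_000)]
    )


@dataclass
class LDBinScheme:
    edges_bp: np.ndarray = field(default_factory=_default_edges)
    min_pairs: int = 50

    def __post_init__(self) -> None:
        self.edges_bp = np.asarray(self.edges_bp)
        if not (np.diff(self.edges_bp) > 0).all():
            raise ValueError("bin edges must be strictly increasing")

    @property
    def max_distance_bp(self) -> int:
        return int(self.edges_bp[-1])

    def labels(self) -> list[str]:
        return [
            f"({lo // 1000},{hi // 1000}]kb"
            for lo, hi in zip(self.edges_bp[:-1], self.edges_bp[1:])
        ]


# ---------------------------------------------------------------------------
# EM haplotype-frequency estimation (vectorized over pairs)
# ---------------------------------------------------------------------------

def _genotype_counts(gA: np.ndarray, gB: np.ndarray) -> np.ndarray:
    """(P, 3, 3) joint genotype counts for P pairs; missing pairs excluded.

    gA, gB: (n, P) dosage arrays.
    """
    ok = (gA != MISSING) & (gB != MISSING)
    counts = np.zeros((gA.shape[1], 3, 3))
    for a in range(3):
        for b in range(3):
            counts[:, a, b] = ((gA == a) & (gB == b) & ok).sum(axis=0)
    return counts


def _em_batch(counts: np.ndarray) -> dict[str, np.ndarray]:
    """EM over P two-locus genotype tables -> haplotype freqs, D, r².

    counts: (P, 3, 3), rows = dosage at locus A, cols = dosage at locus B.
    Haplotype 1 = allele_b.  Monomorphic loci yield r² = NaN.
    """
    counts = np.atleast_3d(counts).reshape(-1, 3, 3)
    P = counts.shape[0]
    n = counts.sum(axis=(1, 2))
    n_safe = np.where(n > 0, n, 1.0)
    # observed allele_b frequencies (EM preserves these margins)
    dosA = counts.sum(axis=2) @ np.array([0.0, 1.0, 2.0])
    dosB = counts.sum(axis=1) @ np.array([0.0, 1.0, 2.0])
    pA = dosA / (2 * n_safe)
    pB = dosB / (2 * n_safe)

    # fixed haplotype-count contributions from unambiguous cells
    c = counts
    fixed11 = 2 * c[:, 2, 2] + c[:, 2, 1] + c[:, 1, 2]
    fixed10 = 2 * c[:, 2, 0] + c[:, 2, 1] + c[:, 1, 0]
    fixed01 = 2 * c[:, 0, 2] + c[:, 0, 1] + c[:, 1, 2]
    fixed00 = 2 * c[:, 0, 0] + c[:, 0, 1] + c[:, 1, 0]
    dh = c[:, 1, 1]  # double heterozygotes: (11 & 00) or (10 & 01)

    # init at linkage equilibrium
    p11 = pA * pB
    p10 = pA * (1 - pB)
    p01 = (1 - pA) * pB
    p00 = (1 - pA) * (1 - pB)
    total = 2 * n_safe
    for _ in range(EM_MAX_ITER):
        num = p11 * p00
        den = num + p10 * p01
        w = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.5)
        n11 = fixed11 + dh * w
        n00 = fixed00 + dh * w
        n10 = fixed10 + dh * (1 - w)
        n01 = fixed01 + dh * (1 - w)
        new11 = n11 / total
        delta = np.abs(new11 - p11).max(initial=0.0)
        p11, p10, p01, p00 = new11, n10 / total, n01 / total, n00 / total
        if delta < EM_TOL:
            break

    D = p11 - pA * pB
    var = pA * (1 - pA) * pB * (1 - pB)
    r2 = np.where(var > 0, D**2 / np.where(var > 0, var, 1.0), np.nan)
    r2 = np.clip(r2, 0.0, 1.0)
    signed_r = np.where(np.isnan(r2), np.nan, np.sign(D) * np.sqrt(r2))
    return {
        "p11": p11, "p10": p10, "p01": p01, "p00": p00,
        "pA": pA, "pB": pB, "D": D, "r2": r2, "signed_r": signed_r, "n": n,
    }


def estimate_haplotype_freqs(gA: np.ndarray, gB: np.ndarray) -> dict[str, float]:
    """EM haplotype-frequency estimate for one SNP pair of dosage vectors.

    Returns p(ab) (both allele_b), p(a), p(b), D, r² and signed_r.  Requires
    at least two individuals called at both loci; a monomorphic locus yields
    r² = NaN (flagged, not raised).
    """
    gA = np.asarray(gA).reshape(-1, 1)
    gB = np.asarray(gB).reshape(-1, 1)
    counts = _genotype_counts(gA, gB)
    if counts.sum() < 2:
        raise ValueError("need >= 2 individuals with both loci called")
    res = _em_batch(counts)
    return {k: float(v[0]) for k, v in res.items()}


# ---------------------------------------------------------------------------
# pair enumeration and binned decay
# ---------------------------------------------------------------------------

def _enumerate_pairs(
    panel: GenotypePanel,
    max_distance_bp: int,
    max_pairs_per_chrom: int | None,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Intra-chromosome SNP index pairs (i, j) with 0 < dist <= max, plus dist."""
    chrom = panel.variants["chrom"].to_numpy()
    pos = panel.variants["pos_bp"].to_numpy()
    ii, jj = [], []
    for c in np.unique(chrom):
        idx = np.nonzero(chrom == c)[0]
        p = pos[idx]
        hi = np.searchsorted(p, p + max_distance_bp, side="right")
        ci, cj = [], []
        for a in range(len(idx)):
            if hi[a] > a + 1:
                cj.append(np.arange(a + 1, hi[a]))
                ci.append(np.full(hi[a] - a - 1, a))
        if not ci:
            continue
        ci = np.concatenate(ci)
        cj = np.concatenate(cj)
        if max_pairs_per_chrom is not None and len(ci) > max_pairs_per_chrom:
            sel = rng.choice(len(ci), size=max_pairs_per_chrom, replace=False)
            sel.sort()
            ci, cj = ci[sel], cj[sel]
        ii.append(idx[ci])
        jj.append(idx[cj])
    if not ii:
        empty = np.empty(0, dtype=int)
        return empty, empty, empty
    ii = np.concatenate(ii)
    jj = np.concatenate(jj)
    return ii, jj, pos[jj] - pos[ii]


def _pair_ld(panel: GenotypePanel, ii: np.ndarray, jj: np.ndarray,
             batch: int = 20_000) -> dict[str, np.ndarray]:
    """EM LD statistics for the given SNP index pairs (batched)."""
    out: dict[str, list] = {}
    for s in range(0, len(ii), batch):
        gA = panel.dosages[:, ii[s: s + batch]]
        gB = panel.dosages[:, jj[s: s + batch]]
        res = _em_batch(_genotype_counts(gA, gB))
        for k, v in res.items():
            out.setdefault(k, []).append(v)
    return {k: np.concatenate(v) if v else np.empty(0) for k, v in out.items()}


def ld_decay(
    panel: GenotypePanel,
    scheme: LDBinScheme | None = None,
    max_pairs_per_chrom: int | None = 200_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Binned mean r² against inter-marker distance, plus overall mean/SD.

    Intra-chromosome pairs only; bins with fewer than ``scheme.min_pairs``
    pairs are suppressed from the binned table (column ``reported`` False).
    """
    scheme = scheme or LDBinScheme()
    rng = np.random.default_rng(seed)
    ii, jj, dist = _enumerate_pairs(panel, scheme.max_distance_bp, max_pairs_per_chrom, rng)
    if len(ii) == 0:
        return (
            pd.DataFrame(columns=["bin_low_bp", "bin_high_bp", "n_pairs", "mean_r2", "reported"]),
            {"mean_r2": np.nan, "sd_r2": np.nan, "n_pairs": 0},
        )
    res = _pair_ld(panel, ii, jj)
    r2 = res["r2"]
    ok = ~np.isnan(r2)
    r2, dist = r2[ok], dist[ok]
    which = np.searchsorted(scheme.edges_bp, dist, side="left") - 1  # (lo, hi]
    rows = []
    for b in range(len(scheme.edges_bp) - 1):
        sel = which == b
        n_b = int(sel.sum())
        rows.append(
            {
                "bin_low_bp": int(scheme.edges_bp[b]),
                "bin_high_bp": int(scheme.edges_bp[b + 1]),
                "n_pairs": n_b,
                "mean_r2": float(r2[sel].mean()) if n_b else np.nan,
                "reported": n_b >= scheme.min_pairs,
            }
        )
    overall = {
        "mean_r2": float(r2.mean()) if len(r2) else np.nan,
        "sd_r2": float(r2.std(ddof=1)) if len(r2) > 1 else np.nan,
        "n_pairs": int(len(r2)),
    }
    return pd.DataFrame(rows), overall


def ne_from_ld(
    bins: pd.DataFrame,
    alpha: int = 1,
    cM_per_Mb: float = 1.0,
    sample_n: int | None = None,
) -> pd.DataFrame:
    """Sved inversion of binned mean r² to Ne(T).

    Distance per bin is the bin midpoint unless a ``distance_bp`` column is
    given.  c = distance_bp · cM_per_Mb · 1e-8 Morgans, T = 1/(2c);
    Ne = (1/(4c))(1/r²_adj − α) with the optional small-sample correction
    r²_adj = r² − 1/(2·sample_n).  Bins whose adjusted r² ≤ 0 are dropped.
    """
    if alpha not in (1, 2):
        raise ValueError("alpha must be 1 (no mutation) or 2")
    bins = bins.copy()
    if "distance_bp" not in bins.columns:
        bins["distance_bp"] = 0.5 * (bins["bin_low_bp"] + bins["bin_high_bp"])
    if "reported" in bins.columns:
        bins = bins.loc[bins["reported"]]
    r2 = bins["mean_r2"].to_numpy(dtype=float)
    if sample_n is not None:
        r2 = r2 - 1.0 / (2.0 * sample_n)
    c = bins["distance_bp"].to_numpy(dtype=float) * cM_per_Mb * 1e-8
    ok = (r2 > 0) & (c > 0)
    if not ok.all():
        import warnings

        warnings.warn(f"dropping {int((~ok).sum())} bins with non-positive adjusted r2")
    out = pd.DataFrame(
        {
            "distance_bp": bins["distance_bp"].to_numpy()[ok],
            "c_morgan": c[ok],
            "T_generations": 1.0 / (2.0 * c[ok]),
            "mean_r2": bins["mean_r2"].to_numpy()[ok],
            "Ne": (1.0 / (4.0 * c[ok])) * (1.0 / r2[ok] - alpha),
        }
    )
    return out


def gametic_phase_consistency(
    panelA: GenotypePanel,
    panelB: GenotypePanel,
    scheme: LDBinScheme | None = None,
    max_pairs_per_chrom: int | None = 200_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-distance-bin Pearson correlation of signed r between two panels.

    Panels are intersected (shared SNPs, harmonized orientation) first; the
    same SNP pairs are evaluated in both.  Pairs with undefined r² in either
    panel are dropped; bins under ``min_pairs`` are suppressed.
    """
    scheme = scheme or LDBinScheme()
    a, b = intersect_panels(panelA, panelB)
    rng = np.random.default_rng(seed)
    ii, jj, dist = _enumerate_pairs(a, scheme.max_distance_bp, max_pairs_per_chrom, rng)
    if len(ii) == 0:
        raise ValueError("no intra-chromosome SNP pairs within the bin range")
    sA = _pair_ld(a, ii, jj)["signed_r"]
    sB = _pair_ld(b, ii, jj)["signed_r"]
    ok = ~(np.isnan(sA) | np.isnan(sB))
    sA, sB, dist = sA[ok], sB[ok], dist[ok]
    which = np.searchsorted(scheme.edges_bp, dist, side="left") - 1
    rows = []
    for bi in range(len(scheme.edges_bp) - 1):
        sel = which == bi
        n_b = int(sel.sum())
        if n_b >= max(scheme.min_pairs, 2) and np.std(sA[sel]) > 0 and np.std(sB[sel]) > 0:
            corr = float(np.corrcoef(sA[sel], sB[sel])[0, 1])
            reported = n_b >= scheme.min_pairs
        else:
            corr, reported = np.nan, False
        rows.append(
            {
                "bin_low_bp": int(scheme.edges_bp[bi]),
                "bin_high_bp": int(scheme.edges_bp[bi + 1]),
                "n_pairs": n_b,
                "correlation": corr,
                "reported": reported,
            }
        )
    return pd.DataFrame(rows)
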