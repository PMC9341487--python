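"""Between-population distances, neighbor-joining trees and supervised
ancestry estimation.

Reynolds' distance is the drift-timescale co-ancestry coefficient θ between
two populations, estimated from allele frequencies with a small-sample
correction and aggregated over SNPs as a ratio of sums.  The
neighbor-joining tree (Saitou–Nei) built from the pairwise θ matrix gives
the breed phylogeny; supervised ancestry fractions come from maximizing the
ADMIXTURE binomial likelihood with founder allele frequencies held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import GenotypePanel, allele_frequencies

_FREQ_EPS = 1e-6


# ---------------------------------------------------------------------------
# Reynolds distance
# ---------------------------------------------------------------------------

def reynolds_distance(
    freqsA: np.ndarray,
    freqsB: np.ndarray,
    countsA: int,
    countsB: int,
) -> float:
    """Reynolds–Weir–Cockerham co-ancestry θ between two populations.

    freqs: per-SNP allele_b frequencies; counts: diploid sample sizes.
    Per-SNP numerator a_l = (p_A − p_B)² minus the sampling-variance
    correction p q /(2n − 1) for each population; denominator a_l + b_l with
    b_l the within-population heterozygosity term.  Numerators and
    denominators are summed across SNPs before the ratio (ratio of sums);
    the result is clamped at 0.
    """
    pA = np.asarray(freqsA, dtype=float)
    pB = np.asarray(freqsB, dtype=float)
    if pA.shape != pB.shape or pA.size == 0:
        raise ValueError("frequency vectors must be non-empty and congruent")
    nA, nB = float(countsA), float(countsB)
    corrA = pA * (1 - pA) / (2 * nA - 1)
    corrB = pB * (1 - pB) / (2 * nB - 1)
    al = (pA - pB) ** 2 - corrA - corrB
    bl = pA * (1 - pA) * 2 * nA / (2 * nA - 1) + pB * (1 - pB) * 2 * nB / (2 * nB - 1)
    den = (al + bl).sum()
    if den <= 0:
        return 0.0
    return float(max(0.0, al.sum() / den))


def distance_matrix(
    panels: dict[str, GenotypePanel],
    region: tuple[int, int, int] | None = None,
) -> pd.DataFrame:
    """Pairwise Reynolds θ between named panels sharing a variant map.

    ``region`` (chrom, start_bp, end_bp) restricts the SNPs used (for
    region-specific trees).
    """
    names = list(panels)
    freqs, counts = {}, {}
    for name, p in panels.items():
        if region is not None:
            c, lo, hi = region
            v = p.variants
            idx = np.nonzero(
                ((v["chrom"] == c) & (v["pos_bp"] >= lo) & (v["pos_bp"] <= hi)).to_numpy()
            )[0]
            if len(idx) == 0:
                raise ValueError(f"region {region} covers no SNPs in panel {name}")
            p = p.subset_variants(idx)
        freqs[name] = allele_frequencies(p)
        counts[name] = p.n_individuals
    D = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            d = reynolds_distance(freqs[a], freqs[b], counts[a], counts[b])
            D.loc[a, b] = D.loc[b, a] = d
    return D


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class PhyloTree:
    """Unrooted NJ tree as a Newick string (+ clamp notes)."""

    newick: str
    notes: list[str] = field(default_factory=list)

    def dendropy_tree(self):
        import dendropy

        return dendropy.Tree.get(data=self.newick, schema="newick")

    def leaf_distances(self) -> pd.DataFrame:
        """Pairwise patristic distances between leaves (for round-trip tests)."""
        tree = self.dendropy_tree()
        pdm = tree.phylogenetic_distance_matrix()
        taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
        out = pd.DataFrame(0.0, index=[t.label for t in taxa], columns=[t.label for t in taxa])
        for i, ta in enumerate(taxa):
            for tb in taxa[i + 1:]:
                d = pdm.patristic_distance(ta, tb)
                out.loc[ta.label, tb.label] = out.loc[tb.label, ta.label] = d
        return out


def neighbor_joining(dm: pd.DataFrame) -> PhyloTree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Q-criterion ties are broken by the smallest (row, col) label-index pair;
    negative branch lengths are clamped to 0 (noted in ``tree.notes``).
    Recovers additive metrics exactly.
    """
    labels = list(dm.index)
    D = dm.to_numpy(dtype=float).copy()
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes = [f"{_escape(l)}" for l in labels]
    notes: list[str] = []

    def clamp(x: float, what: str) -> float:
        if x < 0:
            notes.append(f"negative branch length {x:.6g} at {what} clamped to 0")
            return 0.0
        return x

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # smallest Q; ties -> smallest (i, j)
        flat = np.argmin(Q)
        qmin = Q.flat[flat]
        ties = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-15))
        i_, j_ = min((min(a, b), max(a, b)) for a, b in ties)
        i, j = active[i_], active[j_]
        dij = D[i, j]
        li = clamp(0.5 * dij + (r[i_] - r[j_]) / (2 * (m - 2)), nodes[i])
        lj = clamp(dij - (0.5 * dij + (r[i_] - r[j_]) / (2 * (m - 2))), nodes[j])
        new = len(nodes)
        nodes.append(f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})")
        # distances from the new node
        newrow = np.zeros(new + 1)
        D = np.pad(D, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            D[new, k] = D[k, new] = 0.5 * (D[i, k] + D[j, k] - dij)
        active = [k for k in active if k not in (i, j)] + [new]

    a, b, c = active
    # three-point formulas for the final star
    la = clamp(0.5 * (D[a, b] + D[a, c] - D[b, c]), nodes[a])
    lb = clamp(0.5 * (D[a, b] + D[b, c] - D[a, c]), nodes[b])
    lc = clamp(0.5 * (D[a, c] + D[b, c] - D[a, b]), nodes[c])
    newick = f"({nodes[a]}:{la:.10g},{nodes[b]}:{lb:.10g},{nodes[c]}:{lc:.10g});"
    return PhyloTree(newick=newick, notes=notes)


def _escape(label: str) -> str:
    return str(label).replace(" ", "_").replace("(", "").replace(")", "").replace(",", "_")


# ---------------------------------------------------------------------------
# supervised admixture
# ---------------------------------------------------------------------------

@dataclass
class AncestryEstimate:
    Q: pd.DataFrame  # individuals x K, rows on the simplex
    F: pd.DataFrame  # K x SNPs founder allele_b frequencies (fixed input)
    loglik_trace: list[float]


def supervised_admixture(
    panel: GenotypePanel,
    founder_freqs: pd.DataFrame,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> AncestryEstimate:
    """Supervised ancestry fractions under the binomial admixture likelihood.

    founder_freqs: K x n_snps DataFrame (rows = founder populations) of
    allele_b frequencies, held fixed (clamped to [1e-6, 1−1e-6]).  Per
    individual i, maximize Σ_j [g_ij ln p_ij + (2 − g_ij) ln(1 − p_ij)] with
    p_ij = Σ_k q_ik f_kj by EM on the simplex; the likelihood is monotone
    non-decreasing per iteration.  Missing genotypes are skipped.
    """
    F = founder_freqs.to_numpy(dtype=float)
    if F.shape[0] < 2:
        raise ValueError("need K >= 2 founder populations")
    if F.shape[1] != panel.n_snps:
        raise ValueError("founder_freqs SNP dimension does not match the panel")
    F = np.clip(F, _FREQ_EPS, 1 - _FREQ_EPS)
    G = panel.dosages.astype(float)
    obs = panel.dosages != -1
    Gm = np.where(obs, G, 0.0)
    G2m = np.where(obs, 2.0 - G, 0.0)
    n, m = G.shape
    K = F.shape[0]
    Q = np.full((n, K), 1.0 / K)
    m_i = obs.sum(axis=1).astype(float)

    def loglik(Q_: np.ndarray) -> float:
        P = np.clip(Q_ @ F, _FREQ_EPS, 1 - _FREQ_EPS)
        return float((Gm * np.log(P) + G2m * np.log(1 - P)).sum())

    trace = [loglik(Q)]
    for _ in range(max_iter):
        P = np.clip(Q @ F, _FREQ_EPS, 1 - _FREQ_EPS)
        A = Gm / P          # (n, m)
        B = G2m / (1 - P)
        Q_new = Q * (A @ F.T + B @ (1 - F).T) / (2.0 * m_i[:, None])
        Q_new /= Q_new.sum(axis=1, keepdims=True)
        ll = loglik(Q_new)
        if not np.isfinite(ll):
            raise FloatingPointError("non-finite admixture likelihood")
        Q = Q_new
        improvement = ll - trace[-1]
        trace.append(ll)
        if abs(improvement) < tol:
            break
    return AncestryEstimate(
        Q=pd.DataFrame(Q, index=panel.samples["iid"].to_numpy(), columns=founder_freqs.index),
        F=pd.DataFrame(F, index=founder_freqs.index, columns=founder_freqs.columns),
        loglik_trace=trace,
    )
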