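"""VanRaden genomic relationship matrix, PCA, and frequency-based genomic
inbreeding estimators.

Four estimators are provided, all referenced to sample (or supplied) allele
frequencies p_i with h_i = 2 p_i (1 − p_i):

* ``hom1`` — excess homozygosity via heterozygote counts,
  F = 1 − O_het / E_het (PLINK ``--het`` convention);
* ``grm``  — diagonal of the VanRaden matrix, per-SNP (x − 2p)² / h − 1;
* ``hom2`` — per-SNP 1 − x (2 − x) / h;
* ``uni``  — correlation of uniting gametes, per-SNP
  [x² − (1 + 2p) x + 2p²] / h.

Per-SNP ratios are aggregated as the mean over an individual's non-missing
SNPs (``aggregate="mean"``, the GCTA convention) or as ratio-of-sums
(``aggregate="sum"``, which makes F_GRM equal diag(G) − 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypePanel, allele_frequencies

GENOMIC_METHODS = ("hom1", "grm", "hom2", "uni")


@dataclass
class GRMatrix:
    G: np.ndarray
    freqs: np.ndarray
    n_snps: int

    def __post_init__(self) -> None:
        if not np.allclose(self.G, self.G.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")


def _check_polymorphic(p: np.ndarray, panel: GenotypePanel) -> np.ndarray:
    h = 2.0 * p * (1.0 - p)
    if (h <= 0).any():
        bad = panel.variants["snp_id"].iloc[int(np.argmin(h))]
        raise ValueError(
            f"monomorphic SNP {bad} present; run qc_filter (MAF) before GRM/inbreeding"
        )
    return h


def build_grm(panel: GenotypePanel, freqs: np.ndarray | None = None) -> GRMatrix:
    """VanRaden GRM: G = Z Z' / (2 Σ p_i(1−p_i)), Z = M − 2P.

    Missing dosages are imputed to 2p_i before centering, so they contribute
    zero to Z.  ``freqs`` defaults to sample allele frequencies (row sums of
    Z are then 0).
    """
    p = allele_frequencies(panel) if freqs is None else np.asarray(freqs, dtype=float)
    _check_polymorphic(p, panel)
    d = panel.dosages.astype(float)
    d[panel.dosages == MISSING] = np.nan
    Z = d - 2.0 * p
    Z[np.isnan(Z)] = 0.0  # imputed to 2p -> centered value 0
    denom = 2.0 * np.sum(p * (1.0 - p))
    G = Z @ Z.T / denom
    G = 0.5 * (G + G.T)
    return GRMatrix(G=G, freqs=p, n_snps=panel.n_snps)


def pca(grm: GRMatrix, k: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of G: (scores, variance-explained fractions).

    scores[:, j] = eigenvector_j * sqrt(λ_j); negative eigenvalues are
    clipped to 0 before computing variance fractions.
    """
    n = grm.G.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of individuals {n}")
    lam, vec = np.linalg.eigh(grm.G)
    lam, vec = lam[::-1], vec[:, ::-1]
    lam = np.clip(lam, 0.0, None)
    total = lam.sum()
    varexp = lam[:k] / total if total > 0 else np.zeros(k)
    scores = vec[:, :k] * np.sqrt(lam[:k])
    return scores, varexp


def genomic_inbreeding(
    panel: GenotypePanel,
    method: str,
    freqs: np.ndarray | None = None,
    aggregate: str = "mean",
) -> pd.Series:
    """Per-individual genomic inbreeding coefficient (see module docstring).

    Missing genotypes are excluded per individual (not imputed).
    """
    if method not in GENOMIC_METHODS:
        raise ValueError(f"method must be one of {GENOMIC_METHODS}")
    if aggregate not in ("mean", "sum"):
        raise ValueError("aggregate must be 'mean' or 'sum'")
    p = allele_frequencies(panel) if freqs is None else np.asarray(freqs, dtype=float)
    h = _check_polymorphic(p, panel)
    x = panel.dosages.astype(float)
    obs = panel.dosages != MISSING
    m_j = obs.sum(axis=1)
    if (m_j == 0).any():
        raise ValueError("an individual has no non-missing genotypes")

    if method == "hom1":
        o_het = ((panel.dosages == 1) & obs).sum(axis=1)
        e_het = obs @ h
        F = 1.0 - o_het / e_het
    else:
        if method == "grm":
            num = (x - 2.0 * p) ** 2
            if aggregate == "mean":
                per_snp = num / h - 1.0
            else:
                per_snp = None
        elif method == "hom2":
            per_snp = 1.0 - x * (2.0 - x) / h
            num = None
        else:  # uni
            per_snp = (x**2 - (1.0 + 2.0 * p) * x + 2.0 * p**2) / h
            num = None
        if aggregate == "mean":
            per_snp = np.where(obs, per_snp, 0.0)
            F = per_snp.sum(axis=1) / m_j
        else:
            if method == "grm":
                F = np.where(obs, num, 0.0).sum(axis=1) / (obs @ h) - 1.0
            elif method == "hom2":
                F = 1.0 - np.where(obs, x * (2.0 - x), 0.0).sum(axis=1) / (obs @ h)
            else:
                F = np.where(obs, x**2 - (1.0 + 2.0 * p) * x + 2.0 * p**2, 0.0).sum(
                    axis=1
                ) / (obs @ h)
    return pd.Series(F, index=panel.samples["iid"].to_numpy(), name=f"F_{method.upper()}")


def inbreeding_table(
    panel: GenotypePanel, freqs: np.ndarray | None = None, aggregate: str = "mean"
) -> pd.DataFrame:
    """All four frequency-based estimators side by side."""
    return pd.concat(
        [genomic_inbreeding(panel, m, freqs=freqs, aggregate=aggregate) for m in GENOMIC_METHODS],
        axis=1,
    )


def inbreeding_correlations(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations between inbreeding columns.

    Zero-variance columns yield NaN entries (flagged, not raised).
    """
    if len(table) < 3:
        raise ValueError("need at least 3 individuals for correlations")
    return table.corr(method="pearson", min_periods=2)
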