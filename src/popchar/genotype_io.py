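"""PLINK-format genotype I/O, quality control and allele-frequency summaries.

Genotypes live in a :class:`GenotypePanel`: an individuals x SNPs dosage
matrix coded as the count of ``allele_b`` (0, 1, 2; ``-1`` = missing call),
together with a variant map (chromosome, bp position, alleles) and per-sample
population labels.  Only the 29 bovine autosomes are retained; coordinates are
1-based inclusive throughout (PLINK convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1
N_AUTOSOMES = 29

#: chromosome codes dropped silently (with a count) on read
_NON_AUTOSOME_CODES = {"X", "Y", "XY", "MT", "M", "0", "30", "31", "32", "33"}

VARIANT_COLUMNS = ["snp_id", "chrom", "pos_bp", "allele_a", "allele_b"]
SAMPLE_COLUMNS = ["iid", "population"]


class FormatError(ValueError):
    """Malformed or inconsistent PLINK input."""


@dataclass
class GenotypePanel:
    """Dosage matrix plus variant map and sample sheet.

    Parameters
    ----------
    variants : DataFrame with columns snp_id, chrom, pos_bp, allele_a, allele_b
    samples : DataFrame with columns iid, population
    dosages : (n_individuals, n_snps) int8 array; count of allele_b, -1 missing
    haplotypes : optional (n_individuals, 2, n_snps) int8 array of 0/1 alleles
        (1 = allele_b); populated by the synthetic generator, ``None`` for
        array data read from disk.
    """

    variants: pd.DataFrame
    samples: pd.DataFrame
    dosages: np.ndarray
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise FormatError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if self.haplotypes is not None:
            self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
            if self.haplotypes.shape != (len(self.samples), 2, len(self.variants)):
                raise FormatError("haplotype array shape mismatch")

    @property
    def n_individuals(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.variants)

    def copy(self) -> "GenotypePanel":
        return GenotypePanel(
            self.variants.copy(),
            self.samples.copy(),
            self.dosages.copy(),
            None if self.haplotypes is None else self.haplotypes.copy(),
        )

    def subset_variants(self, index: np.ndarray) -> "GenotypePanel":
        """Panel restricted to the variant positions ``index`` (kept order)."""
        index = np.asarray(index)
        return GenotypePanel(
            self.variants.iloc[index],
            self.samples,
            self.dosages[:, index],
            None if self.haplotypes is None else self.haplotypes[:, :, index],
        )


@dataclass
class QCParams:
    min_call_rate: float = 0.90
    min_maf: float = 0.05
    hwe_p_floor: float = 1e-6
    apply_maf_hwe: bool = True

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_maf", "hwe_p_floor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QCReport:
    """Per-rule removal counts, in application order."""

    n_input: int = 0
    removed: dict = field(default_factory=dict)  # rule -> count, insertion order
    n_retained: int = 0

    def as_frame(self) -> pd.DataFrame:
        rows = [{"rule": k, "n_removed": v} for k, v in self.removed.items()]
        rows.append({"rule": "retained", "n_removed": self.n_retained})
        return pd.DataFrame(rows)

    def validate(self) -> None:
        if sum(self.removed.values()) + self.n_retained != self.n_input:
            raise AssertionError("QC report does not account for every SNP")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _parse_chrom(code: str) -> int | None:
    """Autosome number, or None for recognised non-autosome codes."""
    code = str(code).upper()
    if code in _NON_AUTOSOME_CODES:
        return None
    try:
        c = int(code)
    except ValueError:
        raise FormatError(f"unknown chromosome code {code!r}")
    if 1 <= c <= N_AUTOSOMES:
        return c
    raise FormatError(f"unknown chromosome code {code!r}")


def _read_variant_table(path: Path, has_alleles: bool) -> pd.DataFrame:
    names = ["chrom", "snp_id", "cm", "pos_bp"]
    if has_alleles:
        names += ["allele_a", "allele_b"]
    df = pd.read_csv(path, sep=r"\s+", header=None, names=names, dtype=str)
    if df.isna().any().any():
        raise FormatError(f"{path}: wrong column count for {'BIM' if has_alleles else 'MAP'}")
    df["pos_bp"] = df["pos_bp"].astype(np.int64)
    return df


def _drop_non_autosomes(panel: GenotypePanel) -> GenotypePanel:
    chroms = panel.variants["chrom"].map(_parse_chrom)
    keep = (chroms.notna() & (panel.variants["pos_bp"] > 0)).to_numpy()
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} non-autosomal/unplaced SNPs")
    panel.variants["chrom"] = chroms.fillna(0).astype(int)
    return panel.subset_variants(np.nonzero(keep)[0])


def read_panel(prefix: str | Path, format: str = "bed") -> GenotypePanel:
    """Read a PLINK fileset (``prefix.ped/.map`` or ``prefix.bed/.bim/.fam``).

    Non-autosomal and unplaced SNPs are dropped (count reported via a
    warning); variants are then sorted by (chrom, pos) with file order
    preserved among ties.  Dosage counts allele_b of the MAP/BIM record.
    """
    prefix = Path(prefix)
    if format == "bed":
        panel = _read_bed(prefix)
    elif format == "ped":
        panel = _read_ped(prefix)
    else:
        raise ValueError(f"format must be 'ped' or 'bed', got {format!r}")
    # stable sort: keeps file order within identical (chrom, pos)
    order = np.argsort(
        panel.variants["chrom"].to_numpy() * 10**10 + panel.variants["pos_bp"].to_numpy(),
        kind="stable",
    )
    return panel.subset_variants(order)


def _read_ped(prefix: Path) -> GenotypePanel:
    vmap = _read_variant_table(prefix.with_suffix(".map"), has_alleles=False)
    m_total = len(vmap)
    rows, samples = [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m_total:
                raise FormatError(
                    f"PED line for {parts[1] if len(parts) > 1 else '?'} has "
                    f"{len(parts) - 6} allele columns, expected {2 * m_total}"
                )
            samples.append({"iid": parts[1], "population": parts[0]})
            rows.append(parts[6:])
    if not rows:
        raise FormatError(f"{prefix}.ped contains no individuals")
    alleles = np.array(rows, dtype="U8").reshape(len(rows), m_total, 2)

    # infer allele_a/allele_b per SNP: lexicographic among observed non-missing
    allele_a = np.empty(m_total, dtype=object)
    allele_b = np.empty(m_total, dtype=object)
    dosages = np.full((len(rows), m_total), MISSING, dtype=np.int8)
    for j in range(m_total):
        col = alleles[:, j, :]
        obs = np.unique(col[col != "0"])
        if len(obs) > 2:
            raise FormatError(f"SNP {vmap['snp_id'].iloc[j]} has >2 alleles")
        if len(obs) == 2:
            a, b = sorted(obs)
        elif len(obs) == 1:
            a, b = "0", obs[0]  # single observed allele taken as allele_b
        else:
            a, b = "0", "0"
        allele_a[j], allele_b[j] = a, b
        nonmiss = (col != "0").all(axis=1)
        dosages[nonmiss, j] = (col[nonmiss] == b).sum(axis=1)
    vmap = vmap.assign(allele_a=allele_a, allele_b=allele_b)[VARIANT_COLUMNS]
    panel = GenotypePanel(vmap, pd.DataFrame(samples), dosages)
    return _drop_non_autosomes(panel)


_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major
#: 2-bit genotype code -> dosage of allele_b (BIM second allele)
_BED_DECODE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_BED_ENCODE = {0: 0b00, MISSING: 0b01, 1: 0b10, 2: 0b11}


def _read_bed(prefix: Path) -> GenotypePanel:
    bim = _read_variant_table(prefix.with_suffix(".bim"), has_alleles=True)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype=str,
    )
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise FormatError(f"{prefix}.bed: bad magic bytes (expect SNP-major BED)")
    bpv = (n + 3) // 4  # bytes per variant
    body = raw[3:]
    if body.size != m * bpv:
        raise FormatError(
            f"{prefix}.bed: {body.size} data bytes, expected {m} variants x {bpv}"
        )
    codes = (body.reshape(m, bpv)[:, :, None] >> np.array([0, 2, 4, 6], dtype=np.uint8)) & 3
    codes = codes.reshape(m, bpv * 4)[:, :n]  # (m, n)
    dosages = _BED_DECODE[codes].T.copy()  # (n, m)
    variants = bim.drop(columns="cm")[VARIANT_COLUMNS]
    samples = fam.rename(columns={"fid": "population"})[["iid", "population"]]
    panel = GenotypePanel(variants, samples, dosages)
    return _drop_non_autosomes(panel)


def write_panel(panel: GenotypePanel, prefix: str | Path, format: str = "bed") -> None:
    """Write ``prefix.ped/.map`` or ``prefix.bed/.bim/.fam``.

    Guarantees ``read_panel(write_panel(p)) == p`` for dosages, positions and
    ids (see methods note for the PED monomorphic-SNP caveat).
    """
    if panel.n_individuals == 0:
        raise ValueError("cannot write a panel with no individuals")
    if panel.n_snps == 0:
        raise ValueError("cannot write a panel with no SNPs")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    v = panel.variants
    if format == "ped":
        with open(prefix.with_suffix(".map"), "w") as fh:
            for _, row in v.iterrows():
                fh.write(f"{row.chrom}\t{row.snp_id}\t0\t{row.pos_bp}\n")
        allele_chars = np.stack([v["allele_a"].to_numpy(dtype="U8"),
                                 v["allele_b"].to_numpy(dtype="U8")])
        with open(prefix.with_suffix(".ped"), "w") as fh:
            for i, s in panel.samples.iterrows():
                d = panel.dosages[i]
                g1 = np.where(d >= 1, allele_chars[1], allele_chars[0])
                g2 = np.where(d == 2, allele_chars[1], allele_chars[0])
                g1 = np.where(d == MISSING, "0", g1)
                g2 = np.where(d == MISSING, "0", g2)
                cols = [s.population, s.iid, "0", "0", "0", "-9"]
                cols += [x for pair in zip(g1, g2) for x in pair]
                fh.write(" ".join(cols) + "\n")
    elif format == "bed":
        with open(prefix.with_suffix(".bim"), "w") as fh:
            for _, row in v.iterrows():
                fh.write(
                    f"{row.chrom}\t{row.snp_id}\t0\t{row.pos_bp}\t{row.allele_a}\t{row.allele_b}\n"
                )
        with open(prefix.with_suffix(".fam"), "w") as fh:
            for _, s in panel.samples.iterrows():
                fh.write(f"{s.population}\t{s.iid}\t0\t0\t0\t-9\n")
        n, m = panel.n_individuals, panel.n_snps
        bpv = (n + 3) // 4
        code = np.zeros((m, bpv * 4), dtype=np.uint8)
        enc = np.zeros(4, dtype=np.uint8)
        for dos, c in _BED_ENCODE.items():
            enc[dos % 4] = c  # MISSING=-1 -> index 3
        code[:, :n] = enc[panel.dosages.T % 4]
        packed = (
            code.reshape(m, bpv, 4)
            << np.array([0, 2, 4, 6], dtype=np.uint8)
        ).sum(axis=2, dtype=np.uint8)
        with open(prefix.with_suffix(".bed"), "wb") as fh:
            fh.write(_BED_MAGIC)
            fh.write(packed.tobytes())
    else:
        raise ValueError(f"format must be 'ped' or 'bed', got {format!r}")


# ---------------------------------------------------------------------------
# frequencies, HWE, QC
# ---------------------------------------------------------------------------

def allele_frequencies(panel: GenotypePanel) -> np.ndarray:
    """Per-SNP frequency of allele_b over non-missing calls."""
    d = panel.dosages
    nonmiss = d != MISSING
    n_called = nonmiss.sum(axis=0)
    if (n_called == 0).any():
        bad = panel.variants["snp_id"].iloc[int(np.argmin(n_called))]
        raise ValueError(f"SNP {bad} has no non-missing calls")
    return np.where(nonmiss, d, 0).sum(axis=0) / (2.0 * n_called)


def hwe_exact_pvalue(n_aa_hom: int, n_het: int, n_bb_hom: int) -> float:
    """Exact two-sided Hardy–Weinberg test (conditional on allele counts).

    Sums the probabilities of all heterozygote counts whose conditional
    probability does not exceed that of the observed count (Wigginton-style,
    no mid-p).
    """
    if min(n_aa_hom, n_het, n_bb_hom) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_aa_hom + n_het + n_bb_hom
    if n < 1:
        raise ValueError("need at least one genotype")
    n_a = 2 * n_aa_hom + n_het  # minor-orientation irrelevant: symmetric
    hets = np.arange(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2)
    # log P(het = h | n, n_a) up to a constant:
    #   n! / (naa! h! nbb!) * 2^h  with naa = (n_a - h)/2, nbb = n - naa - h
    from scipy.special import gammaln

    naa = (n_a - hets) // 2
    nbb = n - naa - hets
    logp = (
        hets * np.log(2.0)
        - gammaln(naa + 1)
        - gammaln(hets + 1)
        - gammaln(nbb + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    p_obs = p[np.nonzero(hets == n_het)[0][0]]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def _hwe_pvalues(panel: GenotypePanel) -> np.ndarray:
    d = panel.dosages
    out = np.empty(panel.n_snps)
    for j in range(panel.n_snps):
        col = d[:, j]
        out[j] = hwe_exact_pvalue(
            int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
        )
    return out


def qc_filter(panel: GenotypePanel, params: QCParams | None = None) -> tuple[GenotypePanel, QCReport]:
    """Apply the standard SNP filters in fixed order.

    Order: duplicate position (first kept) -> call rate -> MAF -> HWE; the
    last two only when ``params.apply_maf_hwe`` (the ROH/HER input set is the
    call-rate-filtered panel without MAF/HWE pruning).
    """
    params = params or QCParams()
    report = QCReport(n_input=panel.n_snps)

    v = panel.variants
    dup = v.duplicated(subset=["chrom", "pos_bp"], keep="first").to_numpy()
    report.removed["duplicate_position"] = int(dup.sum())
    panel = panel.subset_variants(np.nonzero(~dup)[0])

    call_rate = (panel.dosages != MISSING).mean(axis=0)
    low = call_rate < params.min_call_rate
    report.removed["call_rate"] = int(low.sum())
    panel = panel.subset_variants(np.nonzero(~low)[0])

    if params.apply_maf_hwe:
        if panel.n_snps:
            p = allele_frequencies(panel)
            maf = np.minimum(p, 1 - p)
            drop = maf < params.min_maf
        else:
            drop = np.zeros(0, dtype=bool)
        report.removed["maf"] = int(drop.sum())
        panel = panel.subset_variants(np.nonzero(~drop)[0])

        if panel.n_snps:
            hwe = _hwe_pvalues(panel) < params.hwe_p_floor
        else:
            hwe = np.zeros(0, dtype=bool)
        report.removed["hwe"] = int(hwe.sum())
        panel = panel.subset_variants(np.nonzero(~hwe)[0])

    report.n_retained = panel.n_snps
    report.validate()
    if panel.n_snps == 0:
        raise ValueError("QC removed every SNP; relax the thresholds")
    return panel, report


def maf_spectrum(panel: GenotypePanel) -> pd.DataFrame:
    """SNP counts/proportions in 10 MAF bins of width 0.05 over (0, 0.5].

    Bins are half-open left, closed right: (0, 0.05], (0.05, 0.10], ...;
    monomorphic SNPs (MAF = 0) are reported as a separate row with
    ``proportion`` NaN; proportions sum to 1 over polymorphic SNPs.
    """
    p = allele_frequencies(panel)
    maf = np.minimum(p, 1 - p)
    edges = np.round(np.linspace(0.0, 0.5, 11), 10)
    poly = maf > 0
    idx = np.searchsorted(edges, maf[poly], side="left") - 1  # right-closed
    counts = np.bincount(np.clip(idx, 0, 9), minlength=10)
    n_poly = int(poly.sum())
    rows = [
        {
            "bin_low": edges[i],
            "bin_high": edges[i + 1],
            "count": int(counts[i]),
            "proportion": counts[i] / n_poly if n_poly else np.nan,
        }
        for i in range(10)
    ]
    rows.append(
        {"bin_low": 0.0, "bin_high": 0.0, "count": int((~poly).sum()), "proportion": np.nan}
    )
    out = pd.DataFrame(rows)
    out["bin"] = [f"({r.bin_low:.2f},{r.bin_high:.2f}]" for r in out.itertuples()][:-1] + [
        "monomorphic"
    ]
    return out


def intersect_panels(a: GenotypePanel, b: GenotypePanel) -> tuple[GenotypePanel, GenotypePanel]:
    """Restrict two panels to their shared SNPs, harmonizing allele orientation.

    SNPs are matched by (chrom, pos).  Where b's alleles are swapped relative
    to a's, b's dosages are complemented (x -> 2 - x).  Shared positions whose
    allele pairs neither match nor swap-match are dropped (counted via a
    warning).  Outputs are in a's variant order.
    """
    key_a = a.variants.assign(_ia=np.arange(a.n_snps))
    key_b = b.variants.assign(_ib=np.arange(b.n_snps))
    merged = key_a.merge(key_b, on=["chrom", "pos_bp"], suffixes=("_a", "_b"))
    if merged.empty:
        raise ValueError("panels share no SNP positions")
    same = (merged["allele_a_a"] == merged["allele_a_b"]) & (
        merged["allele_b_a"] == merged["allele_b_b"]
    )
    swapped = (merged["allele_a_a"] == merged["allele_b_b"]) & (
        merged["allele_b_a"] == merged["allele_a_b"]
    )
    keep = same | swapped
    n_mismatch = int((~keep).sum())
    if n_mismatch:
        warnings.warn(f"dropped {n_mismatch} shared SNPs with irreconcilable alleles")
    merged = merged.loc[keep]
    if merged.empty:
        raise ValueError("no shared SNPs with reconcilable alleles")
    ia = merged["_ia"].to_numpy()
    ib = merged["_ib"].to_numpy()
    out_a = a.subset_variants(ia)
    out_b = b.subset_variants(ib)
    flip = swapped.loc[keep].to_numpy()
    if flip.any():
        d = out_b.dosages
        cols = np.nonzero(flip)[0]
        block = d[:, cols]
        nm = block != MISSING
        block[nm] = 2 - block[nm]
        d[:, cols] = block
        vb = out_b.variants.copy()
        vb.loc[vb.index[cols], ["allele_a", "allele_b"]] = vb.loc[
            vb.index[cols], ["allele_b", "allele_a"]
        ].to_numpy()
        out_b = GenotypePanel(vb, out_b.samples, d)
    return out_a, out_b


def merge_panels(panels: list[GenotypePanel]) -> GenotypePanel:
    """Stack individuals from panels sharing an identical variant map."""
    first = panels[0]
    for p in panels[1:]:
        if not (
            p.variants[["chrom", "pos_bp", "allele_a", "allele_b"]]
            .reset_index(drop=True)
            .equals(first.variants[["chrom", "pos_bp", "allele_a", "allele_b"]].reset_index(drop=True))
        ):
            raise ValueError("panels must share an identical variant map; intersect first")
    return GenotypePanel(
        first.variants.copy(),
        pd.concat([p.samples for p in panels], ignore_index=True),
        np.vstack([p.dosages for p in panels]),
    )
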