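"""Synthetic multi-breed genotype, crossing-scheme and pedigree generator.

Founder breeds diverge from a common ancestral population under the
Balding–Nichols model (per-breed allele frequencies Beta-distributed around an
ancestral frequency with variance set by F_ST).  Within-chromosome linkage
disequilibrium is induced by a first-order haplotype-copying Markov chain
whose dependence decays exponentially with inter-SNP distance, so mean r²
decreases with distance while per-SNP marginal frequencies stay exact.

The composite crossing scheme mirrors a two-stage beef-cattle design:
(Charolais x Caracu) and (Angus x Canchim) F1s inter-mated, with Canchim
itself carried as a 5/8 Charolais + 3/8 Nellore composite for breed-fraction
bookkeeping.  Expected composite fractions are therefore
13/32 CHL, 8/32 CAR, 8/32 ANG, 3/32 NEL.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypePanel

DEFAULT_CHROM_LENGTHS_BP = [120_000_000, 100_000_000, 80_000_000]


@dataclass
class FounderModel:
    """Parameters of the diverged-founder simulation.

    fst may be a scalar (shared by all breeds) or one value per breed; it is
    each breed's divergence from the common ancestor, in (0, 1).
    ld_decay_bp is the length scale (bp) of the exponential decay of the
    haplotype-copying probability; larger values -> longer-range LD.
    """

    n_breeds: int = 2
    fst: float | list[float] = 0.1
    n_snps: int = 1000
    chrom_lengths_bp: list[int] = field(default_factory=lambda: list(DEFAULT_CHROM_LENGTHS_BP))
    ancestral_maf_range: tuple[float, float] = (0.05, 0.95)
    ld_decay_bp: float = 50_000.0
    n_individuals: int = 50
    breed_names: list[str] | None = None
    seed: int = 0

    def fst_per_breed(self) -> np.ndarray:
        f = np.broadcast_to(np.asarray(self.fst, dtype=float), (self.n_breeds,)).copy()
        if not ((f > 0) & (f < 1)).all():
            raise ValueError("fst must lie in (0, 1)")
        return f

    def names(self) -> list[str]:
        if self.breed_names is not None:
            if len(self.breed_names) != self.n_breeds:
                raise ValueError("breed_names length mismatch")
            return list(self.breed_names)
        return [f"BREED{k + 1}" for k in range(self.n_breeds)]


@dataclass
class CrossingScheme:
    """Directed mating plan over named populations.

    matings: ordered (child_population, parent_population_1, parent_population_2);
    intermediate populations may be reused as parents of later matings.
    founder_composition maps each founder breed label to its base-breed
    fraction vector, so a composite founder (Canchim) need not be expanded
    into fake ancestors.
    """

    matings: list[tuple[str, str, str]] = field(
        default_factory=lambda: [
            ("F1_CHLxCAR", "CHL", "CAR"),
            ("F1_ANGxCAN", "ANG", "CAN"),
            ("COMPOSITE", "F1_CHLxCAR", "F1_ANGxCAN"),
        ]
    )
    founder_composition: dict = field(
        default_factory=lambda: {
            "CHL": {"CHL": 1.0},
            "CAR": {"CAR": 1.0},
            "ANG": {"ANG": 1.0},
            "CAN": {"CHL": 5 / 8, "NEL": 3 / 8},
        }
    )

    def validate(self, founder_names: set[str]) -> None:
        defined = set(founder_names)
        for child, p1, p2 in self.matings:
            if p1 not in defined or p2 not in defined:
                raise ValueError(f"mating {child}: unknown parent population")
            if child in defined:
                raise ValueError(f"population {child} defined twice (plan must be acyclic)")
            defined.add(child)

    def expected_fractions(self) -> dict[str, dict[str, float]]:
        """Expected base-breed fractions of every population in the plan."""
        frac = {k: dict(v) for k, v in self.founder_composition.items()}
        for _, p1, p2 in self.matings:
            for p in (p1, p2):
                frac.setdefault(p, {p: 1.0})
        for child, p1, p2 in self.matings:
            out: dict[str, float] = {}
            for parent in (p1, p2):
                for breed, x in frac[parent].items():
                    out[breed] = out.get(breed, 0.0) + 0.5 * x
            frac[child] = out
        return frac


def _snp_map(model: FounderModel, rng: np.random.Generator) -> pd.DataFrame:
    """Random sorted SNP positions, allocated to chromosomes by length."""
    lengths = np.asarray(model.chrom_lengths_bp, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("chromosome lengths must be positive")
    probs = lengths / lengths.sum()
    counts = rng.multinomial(model.n_snps, probs)
    records = []
    for c, (n_c, L) in enumerate(zip(counts, lengths), start=1):
        pos = np.sort(rng.choice(np.int64(L) - 1, size=n_c, replace=False)) + 1
        for p in pos:
            records.append((f"snp_{c}_{p}", c, int(p), "A", "B"))
    return pd.DataFrame(records, columns=["snp_id", "chrom", "pos_bp", "allele_a", "allele_b"])


def _copying_haplotypes(
    n_hap: int,
    freqs: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    ld_decay_bp: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Markov haplotype draw: latent uniform reused with prob exp(-d/L).

    allele_j = 1{u_j < p_j}; u_j = u_{j-1} with probability exp(-d_j/L)
    (0 across chromosome boundaries), else a fresh Uniform(0,1).  Marginals
    are exactly Bernoulli(p_j); adjacent-locus correlation decays with d.
    """
    m = len(freqs)
    u = rng.random((n_hap, m))
    d = np.diff(pos).astype(float)
    same_chrom = chrom[1:] == chrom[:-1]
    copy_prob = np.where(same_chrom, np.exp(-np.maximum(d, 0.0) / ld_decay_bp), 0.0)
    reuse = rng.random((n_hap, m - 1)) < copy_prob
    for j in range(1, m):
        r = reuse[:, j - 1]
        u[r, j] = u[r, j - 1]
    return (u < freqs).astype(np.int8)


def simulate_founder_panels(model: FounderModel) -> dict[str, GenotypePanel]:
    """Balding–Nichols founder breeds with intra-chromosome LD.

    Returns one :class:`GenotypePanel` per breed (haplotypes attached), all
    sharing a common variant map.  Deterministic under ``model.seed``.
    """
    rng = np.random.default_rng(model.seed)
    variants = _snp_map(model, rng)
    lo, hi = model.ancestral_maf_range
    p_anc = rng.uniform(lo, hi, size=len(variants))
    fst = model.fst_per_breed()
    chrom = variants["chrom"].to_numpy()
    pos = variants["pos_bp"].to_numpy()
    panels: dict[str, GenotypePanel] = {}
    for k, name in enumerate(model.names()):
        F = fst[k]
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        p_k = rng.beta(a, b)
        haps = _copying_haplotypes(2 * model.n_individuals, p_k, chrom, pos,
                                   model.ld_decay_bp, rng)
        haps = haps.reshape(model.n_individuals, 2, -1)
        samples = pd.DataFrame(
            {"iid": [f"{name}_{i:04d}" for i in range(model.n_individuals)],
             "population": name}
        )
        panels[name] = GenotypePanel(
            variants.copy(), samples, haps.sum(axis=1, dtype=np.int8), haplotypes=haps
        )
    return panels


def _meiosis(
    haps: np.ndarray,
    paints: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    cM_per_Mb: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One gamete from a (2, m) haplotype pair, Haldane crossover model."""
    m = haps.shape[1]
    gamete = np.empty(m, dtype=np.int8)
    paint = np.empty(m, dtype=paints.dtype)
    for c in np.unique(chrom):
        idx = np.nonzero(chrom == c)[0]
        p = pos[idx]
        length_morgan = (p[-1] - p[0]) * cM_per_Mb * 1e-8 if len(p) > 1 else 0.0
        n_x = rng.poisson(length_morgan)
        cuts = np.sort(rng.uniform(p[0], p[-1], size=n_x)) if n_x else np.empty(0)
        phase = (rng.integers(2) + np.searchsorted(cuts, p)) % 2
        gamete[idx] = haps[phase, idx]
        paint[idx] = paints[phase, idx]
    return gamete, paint


def simulate_composite_cross(
    founders: dict[str, GenotypePanel],
    scheme: CrossingScheme | None = None,
    n_offspring: int = 100,
    cM_per_Mb: float = 1.0,
    seed: int = 0,
) -> tuple[GenotypePanel, pd.DataFrame, pd.DataFrame]:
    """Run the crossing plan; return (final panel, pedigree, realized fractions).

    Gametes are formed with Haldane-model crossovers at ``cM_per_Mb``; each
    transmitted allele carries a founder-population paint, so realized
    per-offspring breed fractions come from segment painting (SNP-resolution,
    expanded through composite founder labels).  The pedigree covers every
    simulated animal with founders as the base generation.
    """
    scheme = scheme or CrossingScheme()
    scheme.validate(set(founders))
    rng = np.random.default_rng(seed)
    first = next(iter(founders.values()))
    variants = first.variants
    chrom = variants["chrom"].to_numpy()
    pos = variants["pos_bp"].to_numpy()

    founder_names = sorted(founders)
    pop_index = {name: i for i, name in enumerate(founder_names)}

    # per-population stores of haplotypes, paints, ids, sexes
    haps: dict[str, np.ndarray] = {}
    paints: dict[str, np.ndarray] = {}
    ids: dict[str, list[str]] = {}
    sexes: dict[str, np.ndarray] = {}
    ped_rows: list[dict] = []

    for name, panel in founders.items():
        if panel.haplotypes is None:
            raise ValueError(f"founder panel {name} lacks haplotypes")
        if not panel.variants[["chrom", "pos_bp"]].equals(variants[["chrom", "pos_bp"]]):
            raise ValueError(f"founder panel {name}: incompatible variant map")
        haps[name] = panel.haplotypes
        paints[name] = np.full(
            (panel.n_individuals, 2, panel.n_snps), pop_index[name], dtype=np.int8
        )
        ids[name] = list(panel.samples["iid"])
        sexes[name] = np.tile([1, 2], panel.n_individuals)[: panel.n_individuals]
        for i, iid in enumerate(ids[name]):
            ped_rows.append(
                {"animal": iid, "sire": "0", "dam": "0",
                 "sex": int(sexes[name][i]), "birth_year": 2000, "population": name}
            )

    for gen, (child, pa, pb) in enumerate(scheme.matings, start=1):
        males_a = np.nonzero(sexes[pa] == 1)[0]
        females_b = np.nonzero(sexes[pb] == 2)[0]
        if len(males_a) == 0 or len(females_b) == 0:
            raise ValueError(f"mating {child}: no available sires/dams")
        m = len(variants)
        ch = np.empty((n_offspring, 2, m), dtype=np.int8)
        cp = np.empty((n_offspring, 2, m), dtype=np.int8)
        cids, csex = [], np.tile([1, 2], n_offspring)[:n_offspring]
        for o in range(n_offspring):
            si = rng.choice(males_a)
            di = rng.choice(females_b)
            ch[o, 0], cp[o, 0] = _meiosis(haps[pa][si], paints[pa][si], chrom, pos, cM_per_Mb, rng)
            ch[o, 1], cp[o, 1] = _meiosis(haps[pb][di], paints[pb][di], chrom, pos, cM_per_Mb, rng)
            iid = f"{child}_{o:04d}"
            cids.append(iid)
            ped_rows.append(
                {"animal": iid, "sire": ids[pa][si], "dam": ids[pb][di],
                 "sex": int(csex[o]), "birth_year": 2000 + 2 * gen, "population": child}
            )
        haps[child], paints[child], ids[child], sexes[child] = ch, cp, cids, csex

    final = scheme.matings[-1][0]
    samples = pd.DataFrame({"iid": ids[final], "population": final})
    panel = GenotypePanel(
        variants.copy(), samples, haps[final].sum(axis=1, dtype=np.int8),
        haplotypes=haps[final],
    )

    # realized fractions by segment painting (per-SNP allele-slot proportions),
    # expanded through composite founder labels
    composition = {
        name: scheme.founder_composition.get(name, {name: 1.0}) for name in founder_names
    }
    base_breeds = sorted({b for comp in composition.values() for b in comp})
    frac_rows = []
    for o, iid in enumerate(ids[final]):
        counts = np.bincount(paints[final][o].ravel(), minlength=len(founder_names))
        pop_frac = counts / counts.sum()
        expanded = {b: 0.0 for b in base_breeds}
        for name, f in zip(founder_names, pop_frac):
            for b, w in composition[name].items():
                expanded[b] += f * w
        expanded["animal"] = iid
        frac_rows.append(expanded)
    fractions = pd.DataFrame(frac_rows).set_index("animal")[base_breeds]
    pedigree = pd.DataFrame(ped_rows)
    return panel, pedigree, fractions


# ---------------------------------------------------------------------------
# planted segments
# ---------------------------------------------------------------------------

def _region_index(panel: GenotypePanel, chrom: int, start_bp: int, end_bp: int) -> np.ndarray:
    v = panel.variants
    mask = (v["chrom"] == chrom) & (v["pos_bp"] >= start_bp) & (v["pos_bp"] <= end_bp)
    return np.nonzero(mask.to_numpy())[0]


def plant_homozygous_segment(
    panel: GenotypePanel, individual: int, chrom: int, start_bp: int, end_bp: int
) -> GenotypePanel:
    """Copy one haplotype over the other in the region -> all SNPs homozygous.

    Without stored haplotypes, heterozygous dosages in the region collapse to
    homozygous allele_a (the first haplotype is taken as the template).
    Returns a modified copy; the input panel is untouched.
    """
    idx = _region_index(panel, chrom, start_bp, end_bp)
    out = panel.copy()
    if len(idx) == 0:
        warnings.warn(f"region {chrom}:{start_bp}-{end_bp} covers no SNPs")
        return out
    if out.haplotypes is not None:
        out.haplotypes[individual, 1, idx] = out.haplotypes[individual, 0, idx]
        out.dosages[individual, idx] = out.haplotypes[individual, :, idx].sum(axis=1)
    else:
        d = out.dosages[individual, idx]
        d[d == 1] = 0
        out.dosages[individual, idx] = d
    return out


def plant_heterozygous_segment(
    panel: GenotypePanel, individual: int, chrom: int, start_bp: int, end_bp: int
) -> GenotypePanel:
    """Set every SNP in the region heterozygous (dosage 1). Idempotent."""
    idx = _region_index(panel, chrom, start_bp, end_bp)
    out = panel.copy()
    if len(idx) == 0:
        warnings.warn(f"region {chrom}:{start_bp}-{end_bp} covers no SNPs")
        return out
    out.dosages[individual, idx] = 1
    if out.haplotypes is not None:
        out.haplotypes[individual, 0, idx] = 0
        out.haplotypes[individual, 1, idx] = 1
    return out


# ---------------------------------------------------------------------------
# pedigree drift
# ---------------------------------------------------------------------------

def simulate_pedigree_drift(
    n_per_gen: int,
    n_gens: int,
    n_sires: int,
    seed: int = 0,
    n_dams: int | None = None,
) -> pd.DataFrame:
    """Discrete-generation random-mating pedigree with known expected ΔF.

    Each generation, ``n_sires`` males and ``n_dams`` females (default equal)
    are drawn from the previous generation and mated at random, so
    E[ΔF] ≈ 1/(8 n_sires) + 1/(8 n_dams)  (Wright's unequal-sex-ratio Ne).

    Returns a pedigree table (animal, sire, dam, sex, birth_year, generation)
    with founders in generation 0.
    """
    if n_sires > n_per_gen // 2:
        raise ValueError("n_sires cannot exceed the number of males per generation")
    n_dams = n_sires if n_dams is None else n_dams
    rng = np.random.default_rng(seed)
    rows = []
    sex = np.tile([1, 2], n_per_gen)[:n_per_gen]
    prev = [f"G0_{i:04d}" for i in range(n_per_gen)]
    prev_sex = sex
    for i, a in enumerate(prev):
        rows.append({"animal": a, "sire": "0", "dam": "0", "sex": int(sex[i]),
                     "birth_year": 2000, "generation": 0})
    for g in range(1, n_gens + 1):
        males = [a for a, s in zip(prev, prev_sex) if s == 1]
        females = [a for a, s in zip(prev, prev_sex) if s == 2]
        sires = rng.choice(males, size=min(n_sires, len(males)), replace=False)
        dams = rng.choice(females, size=min(n_dams, len(females)), replace=False)
        cur = [f"G{g}_{i:04d}" for i in range(n_per_gen)]
        for i, a in enumerate(cur):
            rows.append(
                {"animal": a, "sire": str(rng.choice(sires)), "dam": str(rng.choice(dams)),
                 "sex": int(sex[i]), "birth_year": 2000 + g, "generation": g}
            )
        prev, prev_sex = cur, sex
    return pd.DataFrame(rows)
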