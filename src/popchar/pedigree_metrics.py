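"""Pedigree-based inbreeding, ΔF/F_t series, realized Ne, breed composition
and pedigree-completeness measures.

The central quantity is Wright's inbreeding coefficient F, the kinship of an
animal's parents; cohort means of F give the per-generation rate of
inbreeding ΔF = (F_t − F_{t−1})/(1 − F_{t−1}) and the realized effective
population size Ne = 1/(2ΔF).
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

UNKNOWN = 0  # internal code for an unknown parent


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Validated pedigree: records in topological order (parents first).

    table columns: animal, sire, dam, sex, birth_year (sire/dam "0" = unknown).
    Internally animals are renumbered 1..n in topological order; 0 = unknown.
    """

    table: pd.DataFrame
    _code: dict  # animal id -> int code
    sire: np.ndarray  # int codes, index = animal code - 1
    dam: np.ndarray

    @property
    def animals(self) -> list:
        return list(self.table["animal"])

    @property
    def n(self) -> int:
        return len(self.table)

    def founders(self) -> list:
        mask = (self.sire == UNKNOWN) & (self.dam == UNKNOWN)
        return [a for a, m in zip(self.animals, mask) if m]


_UNKNOWN_TOKENS = {"0", "", "NA", "NAN", "NONE", ".", "-"}


def _norm_parent(x) -> str:
    s = str(x).strip()
    return "0" if s.upper() in _UNKNOWN_TOKENS else s


def build_pedigree(df: pd.DataFrame) -> Pedigree:
    """Validate a pedigree table: normalize unknowns, add phantom-parent
    founders, reject cycles, and topologically order records."""
    df = df.copy()
    required = {"animal", "sire", "dam"}
    if not required.issubset(df.columns):
        raise PedigreeError(f"pedigree needs columns {sorted(required)}")
    df["animal"] = df["animal"].astype(str).str.strip()
    df["sire"] = df["sire"].map(_norm_parent)
    df["dam"] = df["dam"].map(_norm_parent)
    if df["animal"].duplicated().any():
        dup = df.loc[df["animal"].duplicated(), "animal"].iloc[0]
        raise PedigreeError(f"duplicate animal record: {dup}")
    known = set(df["animal"])
    for col, default in (("sex", 0), ("birth_year", np.nan)):
        if col not in df.columns:
            df[col] = default
    phantoms = sorted(
        {p for col in ("sire", "dam") for p in df[col] if p != "0" and p not in known}
    )
    if phantoms:
        sys.stderr.write(f"pedigree: adding {len(phantoms)} phantom parents as founders\n")
        extra = pd.DataFrame(
            {"animal": phantoms, "sire": "0", "dam": "0",
             "sex": 0, "birth_year": np.nan}
        )
        df = pd.concat([extra, df], ignore_index=True)

    # Kahn topological sort over parent -> offspring edges
    ids = list(df["animal"])
    idx = {a: i for i, a in enumerate(ids)}
    n = len(ids)
    indeg = np.zeros(n, dtype=int)
    children: list[list[int]] = [[] for _ in range(n)]
    for i, (s, d) in enumerate(zip(df["sire"], df["dam"])):
        if s == ids[i] or d == ids[i]:
            raise PedigreeError(f"cycle detected: {ids[i]} is its own parent")
        for p in (s, d):
            if p != "0":
                children[idx[p]].append(i)
                indeg[i] += 1
    order: list[int] = []
    stack = [i for i in range(n) if indeg[i] == 0]
    while stack:
        i = stack.pop()
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                stack.append(c)
    if len(order) != n:
        cyc = [ids[i] for i in range(n) if indeg[i] > 0][:5]
        raise PedigreeError(f"cycle detected in pedigree involving {cyc}")

    df = df.iloc[order].reset_index(drop=True)
    code = {a: i + 1 for i, a in enumerate(df["animal"])}
    sire = np.array([code.get(p, UNKNOWN) if p != "0" else UNKNOWN for p in df["sire"]])
    dam = np.array([code.get(p, UNKNOWN) if p != "0" else UNKNOWN for p in df["dam"]])
    return Pedigree(df, code, sire, dam)


def load_pedigree(path: str | Path, sep: str | None = None) -> Pedigree:
    """Load a pedigree TSV/CSV with columns animal, sire, dam[, sex, birth_year]."""
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    aliases = {"id": "animal", "birth_date": "birth_year", "year": "birth_year"}
    df = df.rename(columns=aliases)
    return build_pedigree(df)


def wright_inbreeding(ped: Pedigree) -> pd.Series:
    """Per-animal inbreeding F = kinship(sire, dam); founders F = 0.

    Recursive-kinship evaluation with memoization (equivalent to the tabular
    additive-relationship method, without materializing the full A matrix).
    """
    sire, dam = ped.sire, ped.dam
    memo: dict[tuple[int, int], float] = {}

    def kin(a: int, b: int) -> float:
        if a == UNKNOWN or b == UNKNOWN:
            return 0.0
        if a > b:
            a, b = b, a
        key = (a, b)
        if key in memo:
            return memo[key]
        if a == b:
            v = 0.5 * (1.0 + kin(sire[a - 1], dam[a - 1]))
        else:
            # recurse on the topologically later animal (b): its parents
            # precede it, so recursion terminates
            v = 0.5 * (kin(a, sire[b - 1]) + kin(a, dam[b - 1]))
        memo[key] = v
        return v

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 10 * ped.n + 1000))
    try:
        F = np.array([kin(sire[i], dam[i]) for i in range(ped.n)])
    finally:
        sys.setrecursionlimit(old_limit)
    return pd.Series(F, index=ped.animals, name="F_PED")


def tabular_relationship_matrix(ped: Pedigree) -> np.ndarray:
    """Full additive relationship matrix A by the tabular method (oracle-grade;
    O(n²) memory, intended for small pedigrees)."""
    n = ped.n
    A = np.zeros((n + 1, n + 1))  # index 0 = unknown parent (zeros)
    for i in range(1, n + 1):
        s, d = ped.sire[i - 1], ped.dam[i - 1]
        A[i, i] = 1.0 + 0.5 * A[s, d]
        for j in range(1, i):
            A[i, j] = A[j, i] = 0.5 * (A[j, s] + A[j, d])
    return A[1:, 1:]


def cohort_deltaF(ped: Pedigree, cohort_by: str = "birth_year") -> pd.DataFrame:
    """Cohort mean inbreeding F_t and per-step ΔF = (F_t−F_{t−1})/(1−F_{t−1}).

    cohort_by: "birth_year" (overlapping-generation data) or "generation"
    (discrete simulations; requires a `generation` column).
    """
    if cohort_by not in ped.table.columns:
        raise PedigreeError(f"pedigree has no {cohort_by!r} column")
    F = wright_inbreeding(ped).to_numpy()
    cohorts = pd.to_numeric(ped.table[cohort_by], errors="coerce")
    df = pd.DataFrame({"cohort": cohorts, "F": F}).dropna(subset=["cohort"])
    g = df.groupby("cohort")["F"].agg(["mean", "size"]).reset_index()
    g.columns = ["cohort", "mean_F", "n"]
    if len(g) < 2:
        raise PedigreeError("need at least two cohorts to compute ΔF")
    Ft = g["mean_F"].to_numpy()
    dF = np.full(len(g), np.nan)
    dF[1:] = (Ft[1:] - Ft[:-1]) / (1.0 - Ft[:-1])
    g["delta_F"] = dF
    return g


def ne_from_deltaF(deltaF: float) -> float:
    """Realized effective population size Ne = 1/(2ΔF)."""
    if not 0.0 < deltaF < 1.0:
        raise ValueError(f"ΔF must lie in (0, 1), got {deltaF}")
    return 1.0 / (2.0 * deltaF)


def breed_composition(ped: Pedigree, founder_breed: dict) -> pd.DataFrame:
    """Per-animal breed fractions: fraction = ½·sire + ½·dam, founders labeled.

    founder_breed maps each founder to a breed name or to a fraction dict
    (composite founders, e.g. {"CHL": 5/8, "NEL": 3/8}).  Fractions sum to 1
    per animal.
    """
    norm: dict[str, dict[str, float]] = {}
    for a, v in founder_breed.items():
        norm[str(a)] = {str(v): 1.0} if isinstance(v, str) else dict(v)
    breeds = sorted({b for v in norm.values() for b in v})
    bi = {b: j for j, b in enumerate(breeds)}
    n = ped.n
    frac = np.zeros((n + 1, len(breeds)))  # row 0 = unknown parent, unused
    for i in range(1, n + 1):
        s, d = ped.sire[i - 1], ped.dam[i - 1]
        if s == UNKNOWN and d == UNKNOWN:
            a = ped.animals[i - 1]
            if a not in norm:
                raise PedigreeError(f"founder {a} has no breed label")
            for b, x in norm[a].items():
                frac[i, bi[b]] = x
        elif s == UNKNOWN or d == UNKNOWN:
            raise PedigreeError(
                f"animal {ped.animals[i - 1]} has exactly one known parent; "
                "breed composition needs both or neither"
            )
        else:
            frac[i] = 0.5 * (frac[s] + frac[d])
    out = pd.DataFrame(frac[1:], index=ped.animals, columns=breeds)
    if not np.allclose(out.sum(axis=1), 1.0):
        raise PedigreeError("breed fractions do not sum to 1 (bad founder labels)")
    return out


def equivalent_generations(ped: Pedigree) -> pd.Series:
    """Complete-generation equivalents t = Σ over known ancestors (½)^depth.

    Computed by the recursion t(i) = Σ over known parents ½·(1 + t(parent));
    founders have t = 0.
    """
    n = ped.n
    t = np.zeros(n + 1)
    for i in range(1, n + 1):
        v = 0.0
        for p in (ped.sire[i - 1], ped.dam[i - 1]):
            if p != UNKNOWN:
                v += 0.5 * (1.0 + t[p])
        t[i] = v
    return pd.Series(t[1:], index=ped.animals, name="equiv_generations")
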