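"""Independent brute-force oracles used by the test suite.

Every function here recomputes a quantity by direct enumeration or a naive
algorithm, deliberately sharing no code with the package implementation.
"""

from math import comb, inf

import numpy as np


def hwe_enumeration_pvalue(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact HWE p-value by full enumeration of heterozygote counts.

    Conditional probability of each possible het count given allele counts,
    computed with exact integer binomials; two-sided sum of outcomes no more
    probable than the observed one.
    """
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    probs = {}
    denom = comb(2 * n, na)
    for h in range(na % 2, min(na, 2 * n - na) + 1, 2):
        naa = (na - h) // 2
        nbb = n - naa - h
        # multinomial count of genotype configurations * 2^h over C(2n, na)
        probs[h] = (
            comb(n, naa) * comb(n - naa, h) * 2**h / denom
        )
    total = sum(probs.values())
    p_obs = probs[n_ab] / total
    return sum(p for p in (v / total for v in probs.values()) if p <= p_obs * (1 + 1e-12))


def two_locus_ml_r2(counts: np.ndarray) -> float:
    """Grid-search maximizer of the two-locus multinomial likelihood -> r².

    Margins of the haplotype distribution are fixed at the observed allele
    frequencies (any EM fixed point conserves them); the free parameter is
    the coupling haplotype frequency p11, searched on a fine grid and then
    refined by bounded scalar optimization.
    """
    from scipy.optimize import minimize_scalar

    counts = np.asarray(counts, dtype=float).reshape(3, 3)
    n = counts.sum()
    pA = (counts.sum(axis=1) @ [0, 1, 2]) / (2 * n)
    pB = (counts.sum(axis=0) @ [0, 1, 2]) / (2 * n)

    def negll(p11):
        p10 = pA - p11
        p01 = pB - p11
        p00 = 1 - pA - pB + p11
        h = np.array([[p00, p01], [p10, p11]])  # h[a, b], allele at locus A/B
        if (h < -1e-12).any():
            return inf
        h = np.clip(h, 1e-12, 1)
        # genotype probabilities from random union of gametes
        ll = 0.0
        for ga in range(3):
            for gb in range(3):
                if counts[ga, gb] == 0:
                    continue
                prob = 0.0
                for a1 in range(2):
                    for b1 in range(2):
                        a2, b2 = ga - a1, gb - b1
                        if a2 in (0, 1) and b2 in (0, 1):
                            prob += h[a1, b1] * h[a2, b2]
                ll += counts[ga, gb] * np.log(max(prob, 1e-300))
        return -ll

    lo = max(0.0, pA + pB - 1.0)
    hi = min(pA, pB)
    if hi - lo < 1e-12:
        best = lo
    else:
        grid = np.linspace(lo, hi, 2001)
        best = grid[int(np.argmin([negll(x) for x in grid]))]
        span = (hi - lo) / 2000
        res = minimize_scalar(
            negll, bounds=(max(lo, best - span), min(hi, best + span)),
            method="bounded", options={"xatol": 1e-12},
        )
        best = float(res.x)
    D = best - pA * pB
    var = pA * (1 - pA) * pB * (1 - pB)
    return float(D**2 / var) if var > 0 else float("nan")


def naive_roh(g, pos, params):
    """Brute-force sliding-window ROH: enumerate every window explicitly."""
    n = len(g)
    w = params.window_snps
    segments = []
    if n >= w:
        passing = []
        for s in range(n - w + 1):
            win = g[s: s + w]
            passing.append(
                int(np.sum(win == 1)) <= params.window_max_het
                and int(np.sum(win == -1)) <= params.window_max_missing
            )
        in_run = []
        for k in range(n):
            overlapping = [passing[s] for s in range(max(0, k - w + 1), min(k, n - w) + 1)]
            in_run.append(sum(overlapping) / len(overlapping) >= params.window_hit_threshold)
        # maximal stretches
        k = 0
        while k < n:
            if in_run[k]:
                e = k
                while e + 1 < n and in_run[e + 1]:
                    e += 1
                # split at gaps
                pieces, start = [], k
                for j in range(k + 1, e + 1):
                    if pos[j] - pos[j - 1] > params.max_gap_bp:
                        pieces.append((start, j - 1))
                        start = j
                pieces.append((start, e))
                for bs, be in pieces:
                    n_snps = be - bs + 1
                    length = pos[be] - pos[bs]
                    if (
                        n_snps >= params.min_snps
                        and length >= params.min_length_bp
                        and length / n_snps <= params.min_density_bp_per_snp
                    ):
                        segments.append((int(pos[bs]), int(pos[be]), n_snps))
                k = e + 1
            else:
                k += 1
    return segments


def ancestor_walk_equiv_generations(parents: dict, animal: str) -> float:
    """Σ over all known ancestors of (1/2)^depth, by explicit graph walk."""
    total = 0.0
    frontier = [(animal, 0)]
    while frontier:
        a, depth = frontier.pop()
        for p in parents.get(a, ("0", "0")):
            if p != "0":
                total += 0.5 ** (depth + 1)
                frontier.append((p, depth + 1))
    return total


def random_pedigree(rng, n_founders=6, n_extra=24, missing_parent_rate=0.2):
    """Random acyclic pedigree table rows (animal, sire, dam, sex, birth_year)."""
    rows = []
    animals = []
    for i in range(n_founders):
        a = f"F{i}"
        rows.append({"animal": a, "sire": "0", "dam": "0", "sex": 1 + i % 2,
                     "birth_year": 2000})
        animals.append(a)
    for i in range(n_extra):
        a = f"A{i}"
        sire = dam = "0"
        if rng.random() > missing_parent_rate:
            sire = animals[int(rng.integers(len(animals)))]
            dam = animals[int(rng.integers(len(animals)))]
            while dam == sire:
                dam = animals[int(rng.integers(len(animals)))]
        rows.append({"animal": a, "sire": sire, "dam": dam, "sex": 1 + i % 2,
                     "birth_year": 2001 + i // 5})
        animals.append(a)
    return rows
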