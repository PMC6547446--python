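"""Independent brute-force oracles used to cross-check the library.

Everything here is written as literal loops over genotype lists, sharing no
code with the package implementation.
"""

from __future__ import annotations

import math


def wc_theta_oracle(pop_genotypes: list[list[list[int]]]) -> float:
    """Weir & Cockerham (1984) theta over loci, literal per-locus evaluation.

    ``pop_genotypes[p][l]`` is the list of called ALT doses (0/1/2) for
    population p at locus l. Loci with fewer than 2 called genotypes in any
    population are skipped.
    """
    r = len(pop_genotypes)
    assert r == 2
    n_loci = len(pop_genotypes[0])
    sum_a = 0.0
    sum_abc = 0.0
    for l in range(n_loci):
        ns, ps, hs = [], [], []
        for p in range(r):
            calls = pop_genotypes[p][l]
            n = len(calls)
            ns.append(n)
            if n < 2:
                break
            ps.append(sum(calls) / (2.0 * n))
            hs.append(sum(1 for c in calls if c == 1) / n)
        if min(ns) < 2:
            continue
        n_bar = sum(ns) / r
        n_c = (r * n_bar - sum(n * n for n in ns) / (r * n_bar)) / (r - 1)
        p_bar = sum(n * p for n, p in zip(ns, ps)) / (r * n_bar)
        s2 = sum(n * (p - p_bar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * n_bar)
        h_bar = sum(n * h for n, h in zip(ns, hs)) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2
            - (1.0 / (n_bar - 1))
            * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar)
            - ((r - 1) / r) * s2
            - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
        )
        c = h_bar / 2.0
        sum_a += a
        sum_abc += a + b + c
    return sum_a / sum_abc


def concordance_oracle(
    a: list[list[int]], b: list[list[int]]
) -> dict[str, int]:
    """Cell-by-cell comparison of two equal-shape state grids (-1 = missing)."""
    counts = {
        "comparable": 0, "concordant": 0,
        "hom_hom": 0, "hom_het": 0, "het_hom": 0,
    }
    for row_a, row_b in zip(a, b):
        for x, y in zip(row_a, row_b):
            if x == -1 or y == -1:
                continue
            counts["comparable"] += 1
            if x == y:
                counts["concordant"] += 1
            elif x != 1 and y != 1:
                counts["hom_hom"] += 1
            elif x != 1 and y == 1:
                counts["hom_het"] += 1
            else:
                counts["het_hom"] += 1
    return counts


def maf_oracle(states: list[int]) -> float:
    """Minor allele frequency by explicit allele tally; NaN if nothing called."""
    alleles = []
    for s in states:
        if s == -1:
            continue
        alleles.extend([1] * s + [0] * (2 - s))
    if not alleles:
        return math.nan
    p = sum(alleles) / len(alleles)
    return min(p, 1 - p)


def squared_distance_oracle(dose_i: list[float], dose_j: list[float]) -> float:
    return sum((x - y) ** 2 for x, y in zip(dose_i, dose_j))


def reproducibility_oracle(pair_calls: list[tuple[int, int]]) -> float:
    """Identical / comparable over (call_a, call_b) pairs; NaN if none."""
    comparable = [(x, y) for x, y in pair_calls if x != -1 and y != -1]
    if not comparable:
        return math.nan
    return sum(1 for x, y in comparable if x == y) / len(comparable)
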