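"""Cross-callset comparison: shared-locus partitioning and genotype concordance.

Loci are matched on (contig, position). REF/ALT swaps between callsets are
reconciled by flipping genotype polarity; allele pairs that cannot be
reconciled are excluded and logged. Discordant genotype calls are classified
into three mutually exclusive classes: opposite homozygotes (hom->hom),
hom->het, and het->hom (directional, a->b).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from rrsqc.genotype_store import GenotypeMatrix, HET, HOM_ALT, HOM_REF, MISSING

LocusKey = tuple[str, int]


@dataclass
class SharedLoci:
    """Venn-style partition of the union of loci across callsets."""

    names: list[str]
    partition: dict[tuple[bool, ...], list[LocusKey]]  # membership pattern -> loci
    allele_mismatch: list[LocusKey] = field(default_factory=list)
    flipped: dict[tuple[int, int], set[LocusKey]] = field(default_factory=dict)
    # flipped[(i, j)]: loci where callset j has REF/ALT swapped relative to i

    @property
    def union_size(self) -> int:
        return sum(len(v) for v in self.partition.values()) + len(self.allele_mismatch)

    def intersection(self) -> list[LocusKey]:
        all_in = tuple([True] * len(self.names))
        return list(self.partition.get(all_in, []))

    def counts(self) -> pd.DataFrame:
        rows = []
        for pattern in sorted(self.partition, reverse=True):
            members = "+".join(n for n, m in zip(self.names, pattern) if m)
            rows.append({"callsets": members, "n_loci": len(self.partition[pattern])})
        rows.append({"callsets": "allele_mismatch", "n_loci": len(self.allele_mismatch)})
        return pd.DataFrame(rows)


def shared_loci(
    matrices: Sequence[GenotypeMatrix], names: Sequence[str] | None = None
) -> SharedLoci:
    """Partition the union of locus positions by callset membership.

    For positions present in more than one callset, alleles are cross-checked
    against the first callset carrying the position: identical (REF, ALT)
    passes, a swapped pair is recorded as polarity-flipped, anything else is
    excluded as an allele mismatch.
    """
    if len(matrices) < 2:
        raise ValueError("need at least two callsets")
    if names is None:
        names = [f"callset{i + 1}" for i in range(len(matrices))]
    alleles: list[dict[LocusKey, tuple[str, str]]] = []
    for m in matrices:
        alleles.append(
            {(l.contig, l.position): (l.ref_allele, l.alt_allele) for l in m.loci}
        )
    union = sorted(set().union(*alleles))
    partition: dict[tuple[bool, ...], list[LocusKey]] = {}
    mismatched: list[LocusKey] = []
    flipped: dict[tuple[int, int], set[LocusKey]] = {}
    for key in union:
        pattern = tuple(key in a for a in alleles)
        holders = [i for i, present in enumerate(pattern) if present]
        anchor = holders[0]
        ok = True
        for j in holders[1:]:
            if alleles[j][key] == alleles[anchor][key]:
                continue
            if alleles[j][key] == alleles[anchor][key][::-1]:
                flipped.setdefault((anchor, j), set()).add(key)
            else:
                ok = False
                break
        if ok:
            partition.setdefault(pattern, []).append(key)
        else:
            mismatched.append(key)
    return SharedLoci(list(names), partition, mismatched, flipped)


@dataclass
class ConcordanceRow:
    """Table-row summary of genotype agreement between two callsets."""

    n_shared_loci: int
    n_shared_samples: int
    n_comparable: int  # both-called sample x locus cells
    n_all_shared_cells: int  # all shared sample x locus cells incl. missing
    n_concordant: int
    n_hom_hom: int  # opposite homozygotes
    n_hom_het: int  # hom in a, het in b
    n_het_hom: int  # het in a, hom in b

    def _pct(self, n: int, denom: int) -> float:
        return 100.0 * n / denom if denom else float("nan")

    def rates(self, denominator: str = "comparable") -> dict[str, float]:
        """Percent rates; ``denominator`` is 'comparable' or 'all_shared'."""
        denom = {"comparable": self.n_comparable, "all_shared": self.n_all_shared_cells}[
            denominator
        ]
        return {
            "concordance_pct": self._pct(self.n_concordant, denom),
            "hom_hom_pct": self._pct(self.n_hom_hom, denom),
            "hom_het_pct": self._pct(self.n_hom_het, denom),
            "het_hom_pct": self._pct(self.n_het_hom, denom),
        }


def genotype_concordance(
    matrix_a: GenotypeMatrix,
    matrix_b: GenotypeMatrix,
    shared: Sequence[LocusKey] | None = None,
) -> ConcordanceRow:
    """Cell-by-cell genotype agreement between two callsets.

    Comparable cells are same sample, same locus, both non-missing. REF/ALT
    swapped loci have callset-b genotypes polarity-flipped before comparison.
    """
    if shared is None:
        sl = shared_loci([matrix_a, matrix_b])
        keys = sl.partition.get((True, True), [])
        flip_keys = sl.flipped.get((0, 1), set())
    else:
        keys = list(shared)
        b_alleles = {(l.contig, l.position): (l.ref_allele, l.alt_allele) for l in matrix_b.loci}
        flip_keys = {
            (l.contig, l.position)
            for l in matrix_a.loci
            if (l.contig, l.position) in b_alleles
            and b_alleles[(l.contig, l.position)] == (l.ref_allele, l.alt_allele)[::-1]
        }
        keys = [k for k in keys if k in b_alleles]

    samples = [s for s in matrix_a.samples if s in set(matrix_b.samples)]
    idx_a = {(l.contig, l.position): i for i, l in enumerate(matrix_a.loci)}
    idx_b = {(l.contig, l.position): i for i, l in enumerate(matrix_b.loci)}
    rows_a = np.array([idx_a[k] for k in keys], dtype=int)
    rows_b = np.array([idx_b[k] for k in keys], dtype=int)
    ja = np.array([matrix_a.samples.index(s) for s in samples], dtype=int)
    jb = np.array([matrix_b.samples.index(s) for s in samples], dtype=int)

    if len(keys) == 0 or len(samples) == 0:
        raise ValueError("concordance undefined: zero comparable cells")

    a = matrix_a.states[np.ix_(rows_a, ja)]
    b = matrix_b.states[np.ix_(rows_b, jb)].copy()
    flip_mask = np.array([k in flip_keys for k in keys], dtype=bool)
    called_b = b[flip_mask] != MISSING
    b[flip_mask] = np.where(called_b, 2 - b[flip_mask], MISSING)

    comparable = (a != MISSING) & (b != MISSING)
    n_comparable = int(comparable.sum())
    if n_comparable == 0:
        raise ValueError("concordance undefined: zero comparable cells")
    concordant = comparable & (a == b)
    a_hom = (a == HOM_REF) | (a == HOM_ALT)
    b_hom = (b == HOM_REF) | (b == HOM_ALT)
    discordant = comparable & (a != b)
    hom_hom = discordant & a_hom & b_hom
    hom_het = discordant & a_hom & (b == HET)
    het_hom = discordant & (a == HET) & b_hom
    return ConcordanceRow(
        n_shared_loci=len(keys),
        n_shared_samples=len(samples),
        n_comparable=n_comparable,
        n_all_shared_cells=int(a.size),
        n_concordant=int(concordant.sum()),
        n_hom_hom=int(hom_hom.sum()),
        n_hom_het=int(hom_het.sum()),
        n_het_hom=int(het_hom.sum()),
    )


def concordance_report(
    matrices: Sequence[GenotypeMatrix],
    names: Sequence[str] | None = None,
    denominator: str = "comparable",
) -> pd.DataFrame:
    """Pairwise concordance table over all callset pairs (shared-loci based)."""
    if names is None:
        names = [f"callset{i + 1}" for i in range(len(matrices))]
    rows = []
    for i in range(len(matrices)):
        for j in range(i + 1, len(matrices)):
            row = genotype_concordance(matrices[i], matrices[j])
            entry = {
                "pair": f"{names[i]}:{names[j]}",
                "shared_loci": row.n_shared_loci,
                "shared_samples": row.n_shared_samples,
                "comparable_cells": row.n_comparable,
            }
            entry.update(row.rates(denominator))
            rows.append(entry)
    return pd.DataFrame(rows)
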