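"""Technical-replicate reproducibility, error rate, and deduplication.

Replicate pairs come from the sample sheet's ``replicate_group`` column:
samples sharing a group are technical replicates of one individual, and a
group of size g contributes all g*(g-1)/2 pairs. "Identical call" means the
same genotype state; depths never enter concordance.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from rrsqc.genotype_store import GenotypeMatrix, MISSING, SampleSheet
from rrsqc.qc_filters import FilterEntry, _apply

Pair = tuple[str, str]


def replicate_pairs(sheet: SampleSheet, samples: Sequence[str]) -> list[Pair]:
    """All within-group replicate pairs among ``samples``, deterministic order."""
    present = set(samples)
    pairs: list[Pair] = []
    for _, members in sheet.replicate_groups(samples).items():
        members = [m for m in members if m in present]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                pairs.append((members[i], members[j]))
    return pairs


def _pair_indices(matrix: GenotypeMatrix, pairs: Sequence[Pair]) -> tuple[np.ndarray, np.ndarray]:
    if not pairs:
        raise ValueError("empty replicate pair set")
    pos = {s: j for j, s in enumerate(matrix.samples)}
    try:
        ia = np.array([pos[a] for a, _ in pairs])
        ib = np.array([pos[b] for _, b in pairs])
    except KeyError as exc:
        raise KeyError(f"replicate sample {exc} not present in matrix") from None
    return ia, ib


def _comparable_and_identical(
    matrix: GenotypeMatrix, pairs: Sequence[Pair]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus counts of comparable (both-called) and identical pair-calls."""
    ia, ib = _pair_indices(matrix, pairs)
    a = matrix.states[:, ia]
    b = matrix.states[:, ib]
    comparable = (a != MISSING) & (b != MISSING)
    identical = comparable & (a == b)
    return comparable.sum(axis=1), identical.sum(axis=1)


def locus_reproducibility(matrix: GenotypeMatrix, pairs: Sequence[Pair]) -> np.ndarray:
    """Identical-call fraction over comparable replicate pairs, per locus.

    Loci with zero comparable pairs are undefined and returned as NaN —
    never silently 1.0.
    """
    comparable, identical = _comparable_and_identical(matrix, pairs)
    with np.errstate(invalid="ignore", divide="ignore"):
        rep = identical / comparable
    rep = np.asarray(rep, dtype=float)
    rep[comparable == 0] = np.nan
    return rep


def filter_reproducibility(
    matrix: GenotypeMatrix, pairs: Sequence[Pair], threshold: float = 0.85
) -> tuple[GenotypeMatrix, FilterEntry]:
    """Retain loci with reproducibility strictly above ``threshold``.

    Undefined loci (no comparable pairs) are retained with a warning count:
    absence of evidence is not failure.
    """
    rep = locus_reproducibility(matrix, pairs)
    undefined = int(np.isnan(rep).sum())
    keep = np.isnan(rep) | (rep > threshold)
    out, entry = _apply(
        matrix,
        keep,
        "reproducibility",
        {"min_reproducibility": threshold, "n_pairs": len(pairs)},
        notes={"undefined_retained": undefined},
    )
    if undefined:
        warnings.warn(
            f"{undefined} loci had no comparable replicate pairs and were retained",
            stacklevel=2,
        )
    return out, entry


def error_rate(
    matrix: GenotypeMatrix, pairs: Sequence[Pair], method: str = "pooled"
) -> float:
    """Replicate genotype-call error rate over all comparable pair-calls.

    ``pooled`` (default) micro-averages: discordant / comparable summed over
    loci, which equals 1 minus the comparable-weighted mean locus
    reproducibility. ``mean_locus`` macro-averages the per-locus error rates.
    """
    comparable, identical = _comparable_and_identical(matrix, pairs)
    total = int(comparable.sum())
    if total == 0:
        raise ValueError("error rate undefined: zero comparable replicate calls")
    if method == "pooled":
        return float((comparable - identical).sum() / total)
    if method == "mean_locus":
        rep = locus_reproducibility(matrix, pairs)
        return float(np.nanmean(1.0 - rep))
    raise ValueError(f"unknown method {method!r}")


def reproducibility_table(
    matrix: GenotypeMatrix, pairs: Sequence[Pair]
) -> pd.DataFrame:
    """Per-locus reproducibility with comparable-pair counts."""
    comparable, identical = _comparable_and_identical(matrix, pairs)
    rep = locus_reproducibility(matrix, pairs)
    return pd.DataFrame(
        {
            "locus_id": matrix.locus_ids,
            "comparable_pairs": comparable,
            "identical_pairs": identical,
            "reproducibility": rep,
        }
    )


def deduplicate_replicates(
    matrix: GenotypeMatrix,
    sheet: SampleSheet,
    keep: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Retain one sample per replicate group.

    By default the member with the fewest missing calls wins, ties broken by
    sample-id lexical order. An explicit ``keep`` list overrides the ranking
    (to mirror selecting the same sample across several callsets).
    """
    groups = sheet.replicate_groups(matrix.samples)
    if not groups:
        return matrix.copy()
    keep_set = set(keep) if keep is not None else None
    drop: set[str] = set()
    miss_counts = dict(
        zip(matrix.samples, (matrix.states == MISSING).sum(axis=0).tolist())
    )
    for _, members in groups.items():
        if keep_set is not None:
            chosen = [m for m in members if m in keep_set]
            if len(chosen) != 1:
                raise ValueError(
                    f"keep-list must select exactly one of {members}, got {chosen}"
                )
            winner = chosen[0]
        else:
            winner = min(members, key=lambda s: (miss_counts[s], s))
        drop.update(m for m in members if m != winner)
    return matrix.subset_samples([s for s in matrix.samples if s not in drop])
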