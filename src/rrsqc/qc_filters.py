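"""Per-locus SNP quality filters.

Each filter is a pure operation: it takes a matrix, returns a new matrix with
some loci removed plus a :class:`FilterEntry` describing exactly what was
removed and why. Filters never alter genotype calls, only locus membership,
so they compose freely and a :class:`FilterReport` chain always conserves
locus counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Callable, Sequence

import numpy as np
import pandas as pd

from rrsqc.genotype_store import (
    GenotypeMatrix,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    SampleSheet,
)


class FilterPrerequisiteError(RuntimeError):
    """A filter's inputs are unavailable (no depths, no sexes, no replicates)."""


@dataclass
class FilterEntry:
    """One row of the filter audit trail."""

    filter_name: str
    params: dict[str, Any]
    loci_before: int
    loci_removed: int
    loci_after: int
    removed_ids: list[str] = field(default_factory=list)
    notes: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.loci_after != self.loci_before - self.loci_removed:
            raise ValueError("inconsistent filter entry counts")


@dataclass
class FilterReport:
    """Ordered ledger of applied filters; entries must chain consistently."""

    entries: list[FilterEntry] = field(default_factory=list)

    def add(self, entry: FilterEntry) -> None:
        if self.entries and entry.loci_before != self.entries[-1].loci_after:
            raise ValueError(
                f"report chain broken: {entry.filter_name} starts at "
                f"{entry.loci_before} but previous stage left "
                f"{self.entries[-1].loci_after}"
            )
        self.entries.append(entry)

    @property
    def loci_in(self) -> int | None:
        return self.entries[0].loci_before if self.entries else None

    @property
    def loci_out(self) -> int | None:
        return self.entries[-1].loci_after if self.entries else None

    @property
    def total_removed(self) -> int:
        return sum(e.loci_removed for e in self.entries)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            rows.append(
                {
                    "filter": e.filter_name,
                    "params": ";".join(f"{k}={v}" for k, v in sorted(e.params.items())),
                    "loci_before": e.loci_before,
                    "loci_removed": e.loci_removed,
                    "loci_after": e.loci_after,
                }
            )
        return pd.DataFrame(
            rows,
            columns=["filter", "params", "loci_before", "loci_removed", "loci_after"],
        )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps([asdict(e) for e in self.entries], indent=2)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


@dataclass
class FilterConfig:
    """Thresholds for the full filter chain (defaults follow the protocol)."""

    call_rate_min: float = 0.70
    maf_min: float = 0.01
    max_obs_het: float = 0.70
    min_mean_allele_depth: float = 2.5
    max_coverage_diff: float = 80.0
    min_reproducibility: float = 0.85
    locus_thinning_window: int = 77
    sex_system: str = "XY"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("call_rate_min", "maf_min", "max_obs_het", "min_reproducibility"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not 0.0 <= self.max_coverage_diff <= 200.0:
            raise ValueError("max_coverage_diff must be in [0,200]")
        if self.maf_min > 0.5:
            raise ValueError("maf_min cannot exceed 0.5")
        if self.locus_thinning_window < 1:
            raise ValueError("locus_thinning_window must be >= 1")
        if self.sex_system not in ("XY", "ZW"):
            raise ValueError("sex_system must be 'XY' or 'ZW'")


def _apply(
    matrix: GenotypeMatrix,
    keep: np.ndarray,
    name: str,
    params: dict[str, Any],
    notes: dict[str, Any] | None = None,
) -> tuple[GenotypeMatrix, FilterEntry]:
    removed_ids = [loc.locus_id for loc, k in zip(matrix.loci, keep) if not k]
    entry = FilterEntry(
        filter_name=name,
        params=params,
        loci_before=matrix.n_loci,
        loci_removed=len(removed_ids),
        loci_after=int(keep.sum()),
        removed_ids=removed_ids,
        notes=notes or {},
    )
    return matrix.subset_loci(keep), entry


# ----------------------------------------------------------- per-locus metrics

def call_rate(matrix: GenotypeMatrix) -> np.ndarray:
    """Fraction of samples with a non-missing call, per locus."""
    if matrix.n_samples == 0:
        return np.zeros(matrix.n_loci)
    return (matrix.states != MISSING).mean(axis=1)


def minor_allele_frequency(matrix: GenotypeMatrix) -> np.ndarray:
    """MAF over called genotypes per locus; NaN where nothing is called."""
    called = matrix.states != MISSING
    n_called = called.sum(axis=1)
    alt = np.where(called, matrix.states, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = alt / (2.0 * n_called)
    maf = np.minimum(p_alt, 1.0 - p_alt)
    maf[n_called == 0] = np.nan
    return maf


def observed_heterozygosity(matrix: GenotypeMatrix) -> np.ndarray:
    """Het calls / called genotypes per locus; NaN where nothing is called."""
    called = matrix.states != MISSING
    n_called = called.sum(axis=1)
    het = (matrix.states == HET).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = het / n_called
    ho = np.asarray(ho, dtype=float)
    ho[n_called == 0] = np.nan
    return ho


def mean_allele_depths(matrix: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Mean REF depth over REF carriers and mean ALT depth over ALT carriers.

    Carriers are called genotypes holding at least one copy of the allele
    (hom + het). Loci where an allele has no carriers get NaN for that allele.
    """
    matrix.require_depth("mean_allele_depths")
    ref_carrier = (matrix.states == HOM_REF) | (matrix.states == HET)
    alt_carrier = (matrix.states == HOM_ALT) | (matrix.states == HET)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_ref = np.where(ref_carrier, matrix.depth_ref, 0).sum(axis=1) / ref_carrier.sum(axis=1)
        mean_alt = np.where(alt_carrier, matrix.depth_alt, 0).sum(axis=1) / alt_carrier.sum(axis=1)
    return np.asarray(mean_ref, dtype=float), np.asarray(mean_alt, dtype=float)


def coverage_difference(matrix: GenotypeMatrix) -> np.ndarray:
    """Symmetric percent difference between REF and ALT depth in het calls.

    ``100 * |R - A| / ((R + A) / 2)`` with R, A the mean REF/ALT depths over
    heterozygous calls (allelic imbalance is only observable in hets). Loci
    with no het calls, or zero total het depth, return NaN (no evidence).
    Note the mean-based and summed-depth variants of this formula are
    algebraically identical, since the het-call count cancels.
    """
    matrix.require_depth("coverage_difference")
    het = matrix.states == HET
    n_het = het.sum(axis=1)
    r = np.where(het, matrix.depth_ref, 0).sum(axis=1).astype(float)
    a = np.where(het, matrix.depth_alt, 0).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        diff = 100.0 * np.abs(r - a) / ((r + a) / 2.0)
    diff[(n_het == 0) | (r + a == 0)] = np.nan
    return diff


# ------------------------------------------------------------------- filters

def filter_call_rate(
    matrix: GenotypeMatrix, threshold: float = 0.70
) -> tuple[GenotypeMatrix, FilterEntry]:
    """Retain loci called in at least ``threshold`` of samples (inclusive)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0,1]")
    keep = call_rate(matrix) >= threshold
    return _apply(matrix, keep, "call_rate", {"min_call_rate": threshold})


def filter_maf(
    matrix: GenotypeMatrix, threshold: float = 0.01
) -> tuple[GenotypeMatrix, FilterEntry]:
    """Retain loci with minor allele frequency >= threshold (inclusive).

    Monomorphic loci (MAF 0) are always removed for any threshold > 0; loci
    with zero called genotypes are likewise removed.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("threshold must be in [0,0.5]")
    maf = minor_allele_frequency(matrix)
    keep = np.where(np.isnan(maf), False, maf >= threshold)
    return _apply(matrix, keep, "maf", {"min_maf": threshold})


def filter_max_het(
    matrix: GenotypeMatrix, threshold: float = 0.70
) -> tuple[GenotypeMatrix, FilterEntry]:
    """Retain loci whose observed heterozygosity is <= threshold (inclusive)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0,1]")
    ho = observed_heterozygosity(matrix)
    keep = ~(ho > threshold)  # NaN (no calls) passes: no evidence
    return _apply(matrix, keep, "max_obs_het", {"max_obs_het": threshold})


def filter_allele_depth(
    matrix: GenotypeMatrix, min_mean_depth: float = 2.5
) -> tuple[GenotypeMatrix, FilterEntry]:
    """Retain loci whose mean carrier depth is >= min for both alleles.

    An allele with no carriers fails its criterion, so the locus is removed.
    """
    mean_ref, mean_alt = mean_allele_depths(matrix)
    keep = (
        ~np.isnan(mean_ref)
        & ~np.isnan(mean_alt)
        & (mean_ref >= min_mean_depth)
        & (mean_alt >= min_mean_depth)
    )
    return _apply(
        matrix, keep, "allele_depth", {"min_mean_allele_depth": min_mean_depth}
    )


def filter_coverage_diff(
    matrix: GenotypeMatrix, max_percent: float = 80.0
) -> tuple[GenotypeMatrix, FilterEntry]:
    """Retain loci whose het-call coverage difference is <= max_percent.

    Loci with no heterozygous calls pass: allelic imbalance is unobservable.
    """
    if not 0.0 <= max_percent <= 200.0:
        raise ValueError("max_percent must be in [0,200]")
    diff = coverage_difference(matrix)
    keep = ~(diff > max_percent)  # NaN passes
    return _apply(matrix, keep, "coverage_diff", {"max_coverage_diff": max_percent})


HETEROGAMETIC = {"XY": "male", "ZW": "female"}


def filter_sex_linked(
    matrix: GenotypeMatrix, sheet: SampleSheet, system: str = "XY"
) -> tuple[GenotypeMatrix, FilterEntry, list[str]]:
    """Remove putatively sex-linked loci.

    A locus is flagged iff no heterozygote is called in the heterogametic sex
    (XY: males, ZW: females), at least one heterozygote is called in the
    homogametic sex, and both sexes have at least one called genotype.
    Unknown-sex samples are excluded from both tallies.

    Returns ``(filtered matrix, report entry, flagged locus ids)``.
    """
    if system not in HETEROGAMETIC:
        raise ValueError("system must be 'XY' or 'ZW'")
    sheet.validate_against(matrix)
    sexes = np.array([sheet.sex(s) for s in matrix.samples])
    hetero_sex = HETEROGAMETIC[system]
    homo_sex = "female" if hetero_sex == "male" else "male"
    hetero_cols = sexes == hetero_sex
    homo_cols = sexes == homo_sex
    if not hetero_cols.any() or not homo_cols.any():
        raise FilterPrerequisiteError(
            "sex-linkage filter needs known-sex samples of both sexes "
            f"(found {int(hetero_cols.sum())} {hetero_sex}, "
            f"{int(homo_cols.sum())} {homo_sex})"
        )
    states = matrix.states
    het = states == HET
    called = states != MISSING
    het_in_hetero = het[:, hetero_cols].sum(axis=1)
    het_in_homo = het[:, homo_cols].sum(axis=1)
    called_hetero = called[:, hetero_cols].sum(axis=1)
    called_homo = called[:, homo_cols].sum(axis=1)
    flagged = (
        (het_in_hetero == 0)
        & (het_in_homo >= 1)
        & (called_hetero >= 1)
        & (called_homo >= 1)
    )
    flagged_ids = [loc.locus_id for loc, f in zip(matrix.loci, flagged) if f]
    out, entry = _apply(matrix, ~flagged, "sex_linked", {"system": system})
    return out, entry, flagged_ids


def thin_one_snp_per_locus(
    matrix: GenotypeMatrix, window: int = 77, seed: int = 0
) -> tuple[GenotypeMatrix, FilterEntry]:
    """Keep one randomly chosen SNP per distance-chained cluster.

    SNPs on the same contig are single-linkage chained: consecutive SNPs
    within ``window`` bp share a cluster (emulating one RAD locus). One SNP
    per cluster is retained, chosen uniformly with the given seed;
    deterministic for a fixed seed.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    rng = np.random.default_rng(seed)
    keep = np.zeros(matrix.n_loci, dtype=bool)
    cluster: list[int] = []
    prev_contig: str | None = None
    prev_pos = 0

    def close() -> None:
        if cluster:
            keep[cluster[rng.integers(len(cluster))]] = True

    for i, loc in enumerate(matrix.loci):
        if loc.contig != prev_contig or loc.position - prev_pos > window:
            close()
            cluster = []
        cluster.append(i)
        prev_contig, prev_pos = loc.contig, loc.position
    close()
    return _apply(
        matrix, keep, "thin_one_snp_per_locus", {"window": window, "seed": seed}
    )


# -------------------------------------------------------------------- chains

DEFAULT_ORDER = (
    "allele_depth",
    "coverage_diff",
    "reproducibility",
    "sex_linked",
    "max_obs_het",
    "call_rate",
    "maf",
    "thin",
)


def run_filter_chain(
    matrix: GenotypeMatrix,
    sheet: SampleSheet | None,
    config: FilterConfig,
    order: Sequence[str] = DEFAULT_ORDER,
    *,
    skip_unmet: bool = False,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply filters in ``order``, returning the final matrix and the report.

    With ``skip_unmet`` a stage whose prerequisites are unavailable (depth-free
    matrix, no replicate pairs, no sex data) is recorded as skipped instead of
    raising. Prerequisite failures otherwise propagate with the stage named.
    """
    from rrsqc.replicate_qc import filter_reproducibility, replicate_pairs

    report = FilterReport()
    current = matrix

    def stage(name: str) -> Callable[[GenotypeMatrix], tuple]:
        if name == "allele_depth":
            return lambda m: filter_allele_depth(m, config.min_mean_allele_depth)
        if name == "coverage_diff":
            return lambda m: filter_coverage_diff(m, config.max_coverage_diff)
        if name == "reproducibility":
            def _rep(m: GenotypeMatrix) -> tuple:
                if sheet is None:
                    raise FilterPrerequisiteError("reproducibility needs a sample sheet")
                pairs = replicate_pairs(sheet, m.samples)
                if not pairs:
                    raise FilterPrerequisiteError("no replicate pairs in sample sheet")
                return filter_reproducibility(m, pairs, config.min_reproducibility)
            return _rep
        if name == "sex_linked":
            def _sex(m: GenotypeMatrix) -> tuple:
                if sheet is None:
                    raise FilterPrerequisiteError("sex_linked needs a sample sheet")
                out, entry, _ = filter_sex_linked(m, sheet, config.sex_system)
                return out, entry
            return _sex
        if name == "max_obs_het":
            return lambda m: filter_max_het(m, config.max_obs_het)
        if name == "call_rate":
            return lambda m: filter_call_rate(m, config.call_rate_min)
        if name == "maf":
            return lambda m: filter_maf(m, config.maf_min)
        if name == "thin":
            return lambda m: thin_one_snp_per_locus(
                m, config.locus_thinning_window, config.rng_seed
            )
        raise ValueError(f"unknown filter stage: {name!r}")

    for name in order:
        fn = stage(name)
        try:
            result = fn(current)
        except (FilterPrerequisiteError, RuntimeError) as exc:
            if skip_unmet:
                report.add(
                    FilterEntry(
                        filter_name=name,
                        params={"skipped": True},
                        loci_before=current.n_loci,
                        loci_removed=0,
                        loci_after=current.n_loci,
                        notes={"skipped": str(exc)},
                    )
                )
                continue
            raise type(exc)(f"filter stage {name!r} failed: {exc}") from exc
        current, entry = result[0], result[1]
        report.add(entry)
    return current, report
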