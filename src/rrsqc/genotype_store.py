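"""Core genotype data model and VCF ingestion/export.

Genotype states are stored as an int8 matrix (loci x samples) using the
encoding ``0 = hom_ref, 1 = het, 2 = hom_alt, -1 = missing`` (the non-missing
value doubles as the ALT-allele dose). Per-allele read depths, when present,
are carried in two parallel int32 matrices. Only biallelic SNPs are kept at
ingestion; everything else is excluded and counted, never silently dropped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

_STATE_TO_GT = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
_BASES = frozenset("ACGT")


class VcfFormatError(ValueError):
    """Raised when an input VCF violates the format assumptions."""


class DepthUnavailableError(RuntimeError):
    """Raised when a depth-based operation is requested on a depth-free matrix."""


@dataclass(frozen=True, order=True)
class LocusRecord:
    """Identity of one biallelic SNP locus (VCF 1-based coordinates)."""

    contig: str
    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError(
                f"{self.contig}:{self.position}: only single-base alleles allowed "
                f"(got {self.ref_allele!r}/{self.alt_allele!r})"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.contig}:{self.position}: REF equals ALT")

    @property
    def locus_id(self) -> str:
        return f"{self.contig}:{self.position}"


@dataclass
class IngestionLog:
    """Bookkeeping for records excluded while reading a VCF."""

    n_records: int = 0
    n_retained: int = 0
    n_multiallelic: int = 0
    n_non_snp: int = 0
    n_duplicate: int = 0
    excluded_ids: list[str] = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return self.n_multiallelic + self.n_non_snp + self.n_duplicate


class GenotypeMatrix:
    """Loci x samples diploid genotype matrix with optional allelic depths."""

    def __init__(
        self,
        loci: Sequence[LocusRecord],
        samples: Sequence[str],
        states: np.ndarray,
        depth_ref: np.ndarray | None = None,
        depth_alt: np.ndarray | None = None,
        ingestion: IngestionLog | None = None,
    ) -> None:
        self.loci = list(loci)
        self.samples = list(samples)
        self.states = np.asarray(states, dtype=np.int8)
        self.ingestion = ingestion
        shape = (len(self.loci), len(self.samples))
        if self.states.shape != shape:
            raise ValueError(f"states shape {self.states.shape} != {shape}")
        if not np.isin(self.states, (HOM_REF, HET, HOM_ALT, MISSING)).all():
            raise ValueError("states must be in {-1, 0, 1, 2}")
        if (depth_ref is None) != (depth_alt is None):
            raise ValueError("depth_ref and depth_alt must be supplied together")
        if depth_ref is not None:
            depth_ref = np.asarray(depth_ref, dtype=np.int32)
            depth_alt = np.asarray(depth_alt, dtype=np.int32)
            if depth_ref.shape != shape or depth_alt.shape != shape:
                raise ValueError("depth matrices must match states shape")
            if (depth_ref < 0).any() or (depth_alt < 0).any():
                raise ValueError("depths must be non-negative")
            # depths at missing cells are ignored everywhere; normalise to 0
            miss = self.states == MISSING
            depth_ref = depth_ref.copy()
            depth_alt = depth_alt.copy()
            depth_ref[miss] = 0
            depth_alt[miss] = 0
        self.depth_ref = depth_ref
        self.depth_alt = depth_alt

        ids = [loc.locus_id for loc in self.loci]
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids).value_counts()
            raise ValueError(f"duplicate locus_id: {dup[dup > 1].index[0]}")
        keys = [(loc.contig, loc.position) for loc in self.loci]
        if keys != sorted(keys):
            raise ValueError("loci must be sorted by (contig, position)")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")

    # ------------------------------------------------------------------ shape
    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def has_depth(self) -> bool:
        return self.depth_ref is not None

    @property
    def locus_ids(self) -> list[str]:
        return [loc.locus_id for loc in self.loci]

    def require_depth(self, operation: str) -> None:
        if not self.has_depth:
            raise DepthUnavailableError(
                f"{operation} requires per-allele depths (AD) but the matrix "
                "is depth-free"
            )

    # ---------------------------------------------------------------- subsets
    def subset_loci(self, keep: np.ndarray | Sequence[int]) -> "GenotypeMatrix":
        """New matrix restricted to loci selected by boolean mask or indices."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return GenotypeMatrix(
            [self.loci[i] for i in idx],
            self.samples,
            self.states[idx, :],
            None if self.depth_ref is None else self.depth_ref[idx, :],
            None if self.depth_alt is None else self.depth_alt[idx, :],
        )

    def subset_samples(self, keep: Sequence[str]) -> "GenotypeMatrix":
        """New matrix restricted to the given sample ids (in the given order)."""
        pos = {s: j for j, s in enumerate(self.samples)}
        missing = [s for s in keep if s not in pos]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        idx = np.array([pos[s] for s in keep], dtype=int)
        return GenotypeMatrix(
            self.loci,
            list(keep),
            self.states[:, idx],
            None if self.depth_ref is None else self.depth_ref[:, idx],
            None if self.depth_alt is None else self.depth_alt[:, idx],
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.loci),
            list(self.samples),
            self.states.copy(),
            None if self.depth_ref is None else self.depth_ref.copy(),
            None if self.depth_alt is None else self.depth_alt.copy(),
            ingestion=self.ingestion,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        if self.loci != other.loci or self.samples != other.samples:
            return False
        if not np.array_equal(self.states, other.states):
            return False
        if self.has_depth != other.has_depth:
            return False
        if self.has_depth:
            return np.array_equal(self.depth_ref, other.depth_ref) and np.array_equal(
                self.depth_alt, other.depth_alt
            )
        return True

    def __repr__(self) -> str:
        depth = "with AD" if self.has_depth else "depth-free"
        return (
            f"GenotypeMatrix({self.n_loci} loci x {self.n_samples} samples, {depth})"
        )


@dataclass
class SampleSheet:
    """Sample metadata: population label, sex, optional replicate group."""

    table: pd.DataFrame  # index: sample id; columns: population, sex, replicate_group

    REQUIRED = ("population", "sex")
    SEXES = ("female", "male", "unknown")

    def __post_init__(self) -> None:
        df = self.table
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"sample sheet missing column {col!r}")
        if "replicate_group" not in df.columns:
            df = df.assign(replicate_group=pd.NA)
        df = df.copy()
        df["sex"] = df["sex"].fillna("unknown").astype(str)
        bad = set(df["sex"]) - set(self.SEXES)
        if bad:
            raise ValueError(f"invalid sex values: {sorted(bad)}")
        if df.index.duplicated().any():
            raise ValueError("duplicate sample ids in sample sheet")
        self.table = df

    @classmethod
    def from_records(
        cls,
        populations: Mapping[str, str],
        sexes: Mapping[str, str] | None = None,
        replicate_groups: Mapping[str, str] | None = None,
    ) -> "SampleSheet":
        samples = list(populations)
        df = pd.DataFrame(
            {
                "population": [populations[s] for s in samples],
                "sex": [(sexes or {}).get(s, "unknown") for s in samples],
                "replicate_group": [
                    (replicate_groups or {}).get(s, pd.NA) for s in samples
                ],
            },
            index=pd.Index(samples, name="sample"),
        )
        return cls(df)

    @classmethod
    def read(cls, path: str | Path) -> "SampleSheet":
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
        if "sample" not in df.columns:
            raise ValueError("sample sheet must have a 'sample' column")
        df = df.set_index("sample")
        return cls(df)

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", na_rep="")

    def population(self, sample: str) -> str:
        return str(self.table.at[sample, "population"])

    def sex(self, sample: str) -> str:
        return str(self.table.at[sample, "sex"])

    def populations(self, samples: Iterable[str]) -> pd.Series:
        return self.table.loc[list(samples), "population"]

    def replicate_groups(self, samples: Iterable[str] | None = None) -> dict[str, list[str]]:
        """Map replicate-group id -> member sample ids (restricted to `samples`)."""
        df = self.table
        if samples is not None:
            df = df.loc[df.index.intersection(list(samples))]
        rg = df["replicate_group"].dropna()
        rg = rg[rg.astype(str).str.len() > 0]
        groups: dict[str, list[str]] = {}
        for sample, group in rg.items():
            groups.setdefault(str(group), []).append(str(sample))
        return {g: sorted(members) for g, members in sorted(groups.items())}

    def validate_against(self, matrix: GenotypeMatrix) -> None:
        missing = [s for s in matrix.samples if s not in self.table.index]
        if missing:
            raise KeyError(f"samples absent from sample sheet: {missing}")


# --------------------------------------------------------------------- VCF IO

def read_vcf(path: str | Path, *, min_sample_overlap: float = 0.0) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    Multiallelic sites, non-SNP variants, and duplicate positions are excluded
    and counted in ``matrix.ingestion``. Half-calls map to missing; phase is
    discarded. If the AD format field is absent the matrix is depth-free and
    depth-based filters will refuse to run.

    Parameters
    ----------
    path
        Path to an uncompressed or bgzipped VCF v4.x file with GT calls.
    min_sample_overlap
        Reserved knob for partial-cohort merging; loci called in fewer than
        this fraction of samples are dropped at ingestion (default 0 keeps all).
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path, gts012=True)
    try:
        try:
            vcf.get_header_type("GT")
        except KeyError:
            raise VcfFormatError(f"{path}: VCF has no GT FORMAT field") from None
        try:
            vcf.get_header_type("AD")
            header_has_ad = True
        except KeyError:
            header_has_ad = False

        samples = list(vcf.samples)
        n = len(samples)
        log = IngestionLog()
        loci: list[LocusRecord] = []
        states_rows: list[np.ndarray] = []
        dr_rows: list[np.ndarray] = []
        da_rows: list[np.ndarray] = []
        seen: set[tuple[str, int]] = set()
        prev: tuple[str, int] | None = None
        contigs_done: set[str] = set()
        any_ad = False

        for rec in vcf:
            log.n_records += 1
            key = (rec.CHROM, rec.POS)
            if prev is not None:
                if rec.CHROM == prev[0]:
                    if rec.POS < prev[1]:
                        raise VcfFormatError(
                            f"{path}: unsorted VCF at record {rec.CHROM}:{rec.POS} "
                            f"(follows {prev[0]}:{prev[1]})"
                        )
                elif rec.CHROM in contigs_done:
                    raise VcfFormatError(
                        f"{path}: unsorted VCF at record {rec.CHROM}:{rec.POS} "
                        f"(contig {rec.CHROM} reappears)"
                    )
                else:
                    contigs_done.add(prev[0])
            prev = key

            alts = rec.ALT
            if len(alts) != 1:
                log.n_multiallelic += 1
                log.excluded_ids.append(f"{rec.CHROM}:{rec.POS}")
                continue
            ref, alt = rec.REF.upper(), alts[0].upper()
            if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
                log.n_non_snp += 1
                log.excluded_ids.append(f"{rec.CHROM}:{rec.POS}")
                continue
            if key in seen:
                log.n_duplicate += 1
                log.excluded_ids.append(f"{rec.CHROM}:{rec.POS}")
                continue
            seen.add(key)

            # derive states from raw allele indices so half-calls -> missing
            gts = np.asarray(rec.genotypes, dtype=object)
            row = np.empty(n, dtype=np.int8)
            for j in range(n):
                a = gts[j][:-1]  # last element is the phased flag
                if len(a) != 2 or a[0] < 0 or a[1] < 0:
                    row[j] = MISSING
                else:
                    row[j] = int(a[0] > 0) + int(a[1] > 0)

            dr = np.zeros(n, dtype=np.int32)
            da = np.zeros(n, dtype=np.int32)
            if header_has_ad:
                ad = rec.format("AD")
                if ad is not None and ad.shape[1] >= 2:
                    any_ad = True
                    ad = ad.astype(np.int64)
                    ad[ad < 0] = 0  # cyvcf2 missing sentinel
                    dr = ad[:, 0].astype(np.int32)
                    da = ad[:, 1].astype(np.int32)

            loci.append(LocusRecord(rec.CHROM, rec.POS, ref, alt))
            states_rows.append(row)
            dr_rows.append(dr)
            da_rows.append(da)
    finally:
        vcf.close()

    log.n_retained = len(loci)
    if states_rows:
        states = np.vstack(states_rows)
        depth_ref = np.vstack(dr_rows) if any_ad else None
        depth_alt = np.vstack(da_rows) if any_ad else None
    else:
        states = np.empty((0, n), dtype=np.int8)
        depth_ref = depth_alt = None

    # enforce lexical (contig, position) ordering for the matrix invariant
    order = sorted(range(len(loci)), key=lambda i: (loci[i].contig, loci[i].position))
    loci = [loci[i] for i in order]
    states = states[order, :] if len(order) else states
    if depth_ref is not None:
        depth_ref = depth_ref[order, :]
        depth_alt = depth_alt[order, :]

    if min_sample_overlap > 0 and len(loci):
        called = (states != MISSING).mean(axis=1)
        keep = called >= min_sample_overlap
        loci = [loc for loc, k in zip(loci, keep) if k]
        states = states[keep, :]
        if depth_ref is not None:
            depth_ref = depth_ref[keep, :]
            depth_alt = depth_alt[keep, :]

    if not any_ad:
        warnings.warn(
            f"{path}: no per-allele depth (AD) found; matrix is depth-free and "
            "depth-based filters are disabled",
            stacklevel=2,
        )
    if log.n_excluded:
        logger.info(
            "%s: excluded %d of %d records (%d multiallelic, %d non-SNP, %d duplicate)",
            path, log.n_excluded, log.n_records, log.n_multiallelic,
            log.n_non_snp, log.n_duplicate,
        )
    return GenotypeMatrix(loci, samples, states, depth_ref, depth_alt, ingestion=log)


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a matrix as an uncompressed VCF 4.2 file (GT[:AD]).

    Deterministic byte-for-byte output: round-trips through :func:`read_vcf`
    reproduce states, depths, loci, and sample order exactly.
    """
    path = Path(path)
    lines = ["##fileformat=VCFv4.2", "##source=rrsqc"]
    for contig in dict.fromkeys(loc.contig for loc in matrix.loci):
        lines.append(f"##contig=<ID={contig}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    fmt = "GT"
    if matrix.has_depth:
        lines.append(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths for the ref and alt alleles">'
        )
        fmt = "GT:AD"
    header_cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    lines.append("\t".join(header_cols + matrix.samples))
    for i, loc in enumerate(matrix.loci):
        cells = []
        for j in range(matrix.n_samples):
            gt = _STATE_TO_GT[int(matrix.states[i, j])]
            if matrix.has_depth:
                cells.append(f"{gt}:{matrix.depth_ref[i, j]},{matrix.depth_alt[i, j]}")
            else:
                cells.append(gt)
        lines.append(
            "\t".join(
                [loc.contig, str(loc.position), ".", loc.ref_allele, loc.alt_allele,
                 ".", "PASS", ".", fmt] + cells
            )
        )
    path.write_text("\n".join(lines) + "\n")


def missing_fraction(matrix: GenotypeMatrix) -> tuple[float, pd.Series]:
    """Missing-call fraction for the whole dataset and per sample.

    Returns ``(dataset_fraction, per_sample_series)``; the dataset value is
    missing cells over total cells, so it equals the sample mean weighted by
    locus count.
    """
    miss = matrix.states == MISSING
    total = matrix.states.size
    dataset = float(miss.sum() / total) if total else 0.0
    per_sample = pd.Series(
        miss.mean(axis=0) if matrix.n_loci else np.zeros(matrix.n_samples),
        index=matrix.samples,
        name="missing_fraction",
    )
    return dataset, per_sample
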