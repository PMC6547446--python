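"""Within-population diversity summaries: H_O, H_E, MLH, genotype ratios."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from rrsqc.genotype_store import GenotypeMatrix, HET, HOM_ALT, HOM_REF, MISSING, SampleSheet
from rrsqc.qc_filters import observed_heterozygosity


@dataclass
class DiversitySummary:
    """Per-locus H_O/H_E with dataset-level means and SDs."""

    per_locus: pd.DataFrame  # columns: locus_id, ho, he
    mean_ho: float
    sd_ho: float
    mean_he: float
    sd_he: float
    n_loci: int

    def row(self) -> dict[str, float]:
        return {
            "n_loci": self.n_loci,
            "mean_ho": self.mean_ho,
            "sd_ho": self.sd_ho,
            "mean_he": self.mean_he,
            "sd_he": self.sd_he,
        }


def expected_heterozygosity(
    matrix: GenotypeMatrix, *, unbiased: bool = False
) -> np.ndarray:
    """Per-locus H_E = 2p(1-p) from called allele frequencies.

    With ``unbiased`` the small-sample correction 2n/(2n-1) is applied
    (Nei's unbiased estimator); the default is the uncorrected form.
    Loci with zero called genotypes return NaN.
    """
    called = matrix.states != MISSING
    n_called = called.sum(axis=1)
    alt = np.where(called, matrix.states, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / (2.0 * n_called)
        he = 2.0 * p * (1.0 - p)
        if unbiased:
            he = he * (2.0 * n_called) / (2.0 * n_called - 1.0)
    he = np.asarray(he, dtype=float)
    he[n_called == 0] = np.nan
    return he


def _summarise(matrix: GenotypeMatrix, unbiased: bool) -> DiversitySummary:
    ho = observed_heterozygosity(matrix)
    he = expected_heterozygosity(matrix, unbiased=unbiased)
    per_locus = pd.DataFrame({"locus_id": matrix.locus_ids, "ho": ho, "he": he})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        return DiversitySummary(
            per_locus=per_locus,
            mean_ho=float(np.nanmean(ho)) if len(ho) else float("nan"),
            sd_ho=float(np.nanstd(ho, ddof=1)) if len(ho) > 1 else float("nan"),
            mean_he=float(np.nanmean(he)) if len(he) else float("nan"),
            sd_he=float(np.nanstd(he, ddof=1)) if len(he) > 1 else float("nan"),
            n_loci=matrix.n_loci,
        )


def het_stats(
    matrix: GenotypeMatrix,
    sheet: SampleSheet | None = None,
    *,
    unbiased: bool = False,
) -> DiversitySummary | dict[str, DiversitySummary]:
    """Observed and expected heterozygosity per locus with dataset summaries.

    If ``sheet`` is given, statistics are computed per population by
    subsetting samples and recomputing allele frequencies within each subset,
    and a dict keyed by population label is returned.
    """
    if sheet is None:
        return _summarise(matrix, unbiased)
    sheet.validate_against(matrix)
    pops = sheet.populations(matrix.samples)
    out: dict[str, DiversitySummary] = {}
    for pop in sorted(pops.unique()):
        sub = matrix.subset_samples([s for s in matrix.samples if pops[s] == pop])
        out[str(pop)] = _summarise(sub, unbiased)
    return out


def mlh(matrix: GenotypeMatrix) -> pd.Series:
    """Multilocus heterozygosity: het calls / called loci, per sample.

    Samples with zero called loci are undefined (NaN) and trigger a warning.
    """
    called = (matrix.states != MISSING).sum(axis=0)
    het = (matrix.states == HET).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = het / called
    values = np.asarray(values, dtype=float)
    values[called == 0] = np.nan
    n_undef = int((called == 0).sum())
    if n_undef:
        warnings.warn(f"{n_undef} samples have zero called loci; MLH undefined", stacklevel=2)
    return pd.Series(values, index=matrix.samples, name="mlh")


def genotype_ratios(matrix: GenotypeMatrix) -> tuple[float, float, float]:
    """Dataset proportions of (hom_major, het, hom_minor) among called calls.

    The major homozygote at each locus is the one for the more frequent
    called allele; ties go to REF. Proportions sum to 1 whenever any call
    exists.
    """
    called = matrix.states != MISSING
    n_called = called.sum(axis=1)
    alt = np.where(called, matrix.states, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_ref = 1.0 - alt / (2.0 * n_called)
    ref_major = np.where(n_called > 0, p_ref >= 0.5, True)

    hom_ref_n = (matrix.states == HOM_REF).sum(axis=1)
    hom_alt_n = (matrix.states == HOM_ALT).sum(axis=1)
    het_n = (matrix.states == HET).sum(axis=1)
    hom_major = np.where(ref_major, hom_ref_n, hom_alt_n).sum()
    hom_minor = np.where(ref_major, hom_alt_n, hom_ref_n).sum()
    total = int(n_called.sum())
    if total == 0:
        return (float("nan"),) * 3
    return (
        float(hom_major / total),
        float(het_n.sum() / total),
        float(hom_minor / total),
    )


def summary_table(
    matrix: GenotypeMatrix,
    sheet: SampleSheet | None = None,
    *,
    error_rate: float | None = None,
) -> pd.DataFrame:
    """One-row dataset summary: loci counts, missingness, H_O/H_E, MLH."""
    from rrsqc.genotype_store import missing_fraction

    div = _summarise(matrix, unbiased=False)
    overall, per_sample = missing_fraction(matrix)
    loci_per_sample = (matrix.states != MISSING).sum(axis=0)
    m = mlh(matrix)
    row = {
        "total_loci": matrix.n_loci,
        "n_samples": matrix.n_samples,
        "mean_loci": float(loci_per_sample.mean()) if matrix.n_samples else float("nan"),
        "min_loci": int(loci_per_sample.min()) if matrix.n_samples else 0,
        "max_loci": int(loci_per_sample.max()) if matrix.n_samples else 0,
        "pct_missing": 100.0 * overall,
        "error_rate_pct": 100.0 * error_rate if error_rate is not None else float("nan"),
        "mean_ho": div.mean_ho,
        "sd_ho": div.sd_ho,
        "mean_he": div.mean_he,
        "sd_he": div.sd_he,
        "mean_mlh": float(np.nanmean(m.values)) if matrix.n_samples else float("nan"),
        "sd_mlh": float(np.nanstd(m.values, ddof=1)) if matrix.n_samples > 1 else float("nan"),
    }
    return pd.DataFrame([row])
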