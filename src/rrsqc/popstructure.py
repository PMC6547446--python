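"""Between-population divergence: PCoA and Weir-Cockerham F_ST with bootstrap CIs.

The F_ST estimator is the Weir & Cockerham (1984) theta for biallelic SNPs:
per-locus variance components a (among populations), b (among individuals
within populations) and c (within individuals), combined across loci as
sum(a) / sum(a + b + c). Confidence intervals come from percentile bootstrap
over loci.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from rrsqc.genotype_store import GenotypeMatrix, HET, MISSING, SampleSheet


@dataclass
class PcoaResult:
    """Principal-coordinates embedding of samples."""

    coordinates: pd.DataFrame  # samples x retained axes ("PCo1", ...)
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    percent_variance: np.ndarray  # per retained axis, of the positive total

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


def dosage_matrix(matrix: GenotypeMatrix, *, impute: bool = True) -> np.ndarray:
    """Samples x loci ALT-dose matrix (0/1/2); missing cells mean-imputed.

    Loci that are missing in every sample carry no information and are
    dropped with a warning.
    """
    dose = matrix.states.T.astype(float)  # samples x loci
    dose[dose == MISSING] = np.nan
    all_nan = np.isnan(dose).all(axis=0)
    if all_nan.any():
        warnings.warn(
            f"{int(all_nan.sum())} all-missing loci dropped from dosage matrix",
            stacklevel=2,
        )
        dose = dose[:, ~all_nan]
    if impute and np.isnan(dose).any():
        col_mean = np.nanmean(dose, axis=0)
        nan_r, nan_c = np.nonzero(np.isnan(dose))
        dose[nan_r, nan_c] = col_mean[nan_c]
    return dose


def pcoa(matrix: GenotypeMatrix, *, eps: float = 1e-9) -> PcoaResult:
    """PCoA of samples from squared pairwise Euclidean distances on dosages.

    Missing cells are imputed with the locus mean dose. The squared distance
    matrix is Gower double-centered and eigendecomposed; axes are returned
    only for eigenvalues above ``eps`` x largest, scaled to sqrt(eigenvalue).
    Axis signs are fixed deterministically: each axis is oriented so its
    largest-magnitude coordinate is positive.
    """
    if matrix.n_samples < 2 or matrix.n_loci < 1:
        raise ValueError("pcoa needs >= 2 samples and >= 1 locus")
    dose = dosage_matrix(matrix)
    sq = ((dose[:, None, :] - dose[None, :, :]) ** 2).sum(axis=2)
    n = sq.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ sq @ j
    b = (b + b.T) / 2.0
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    tol = eps * max(abs(eigval[0]), 1.0)
    pos = eigval > tol
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    for k in range(coords.shape[1]):  # deterministic sign convention
        i_max = int(np.argmax(np.abs(coords[:, k])))
        if coords[i_max, k] < 0:
            coords[:, k] = -coords[:, k]
    pos_total = eigval[pos].sum()
    pct = 100.0 * eigval[pos] / pos_total if pos_total > 0 else np.zeros(pos.sum())
    frame = pd.DataFrame(
        coords,
        index=matrix.samples,
        columns=[f"PCo{k + 1}" for k in range(coords.shape[1])],
    )
    return PcoaResult(coordinates=frame, eigenvalues=eigval, percent_variance=pct)


# ------------------------------------------------------------------- F_ST

def _pop_counts(
    matrix: GenotypeMatrix, sheet: SampleSheet, pop_a: str, pop_b: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus called-sample counts, ALT frequencies and het frequencies."""
    sheet.validate_against(matrix)
    pops = sheet.populations(matrix.samples)
    cols = {
        pop: np.array([pops[s] == pop for s in matrix.samples]) for pop in (pop_a, pop_b)
    }
    out = []
    for pop in (pop_a, pop_b):
        states = matrix.states[:, cols[pop]]
        called = states != MISSING
        n = called.sum(axis=1).astype(float)
        if states.shape[1] == 0 or (n == 0).all():
            raise ValueError(f"population {pop!r} has no called genotypes")
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(called, states, 0).sum(axis=1) / (2.0 * n)
            h = (states == HET).sum(axis=1) / n
        out.extend([n, p, h])
    return tuple(out)  # type: ignore[return-value]


def wc_variance_components(
    matrix: GenotypeMatrix, sheet: SampleSheet, pop_a: str, pop_b: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir-Cockerham per-locus components (a, abc, usable) for one pop pair.

    ``a`` is the among-population component, ``abc`` the total a + b + c;
    ``usable`` marks loci with >= 2 called genotypes in both populations
    (others are skipped for this pair).
    """
    n1, p1, h1, n2, p2, h2 = _pop_counts(matrix, sheet, pop_a, pop_b)
    usable = (n1 >= 2) & (n2 >= 2)
    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        n_bar = (n1 + n2) / r
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1.0)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        inner = p_bar * (1.0 - p_bar) - ((r - 1.0) / r) * s2 - h_bar / 4.0
        a = (n_bar / n_c) * (s2 - inner / (n_bar - 1.0))
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1.0 - p_bar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * n_bar - 1.0) / (4.0 * n_bar)) * h_bar
        )
        c = h_bar / 2.0
    a = np.where(usable, a, 0.0)
    abc = np.where(usable, a + b + c, 0.0)
    return np.asarray(a, float), np.asarray(abc, float), usable


def fst_theta(a: np.ndarray, abc: np.ndarray) -> float:
    """Ratio-of-sums combination of W&C components across loci."""
    denom = abc.sum()
    if denom == 0:
        return float("nan")
    return float(a.sum() / denom)


@dataclass
class FstResult:
    """Point estimate and percentile bootstrap CI for one population pair."""

    pop_a: str
    pop_b: str
    estimate: float
    ci_lower: float
    ci_upper: float
    n_boot: int
    n_loci_used: int

    def __post_init__(self) -> None:
        if not (np.isnan(self.ci_lower) or self.ci_lower <= self.ci_upper):
            raise ValueError("bootstrap CI bounds out of order")


def pairwise_fst(
    matrix: GenotypeMatrix,
    sheet: SampleSheet,
    *,
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> list[FstResult]:
    """Weir-Cockerham theta for every population pair with bootstrap CIs.

    Bootstrap resamples loci with replacement ``n_boot`` times; the CI is the
    (alpha/2, 1 - alpha/2) percentile interval of the replicate estimates.
    Deterministic for a fixed seed; invariant to sample and locus order.
    """
    sheet.validate_against(matrix)
    pops = sorted(sheet.populations(matrix.samples).unique())
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    results = []
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            results.append(
                _fst_one_pair(
                    matrix, sheet, pops[i], pops[j],
                    n_boot=n_boot, seed=seed, alpha=alpha,
                )
            )
    return results


def _fst_one_pair(
    matrix: GenotypeMatrix,
    sheet: SampleSheet,
    pop_a: str,
    pop_b: str,
    *,
    n_boot: int,
    seed: int,
    alpha: float,
) -> FstResult:
    a, abc, usable = wc_variance_components(matrix, sheet, pop_a, pop_b)
    a = a[usable]
    abc = abc[usable]
    n_loci = int(usable.sum())
    if n_loci == 0:
        raise ValueError(f"no usable loci for pair {pop_a}:{pop_b}")
    est = fst_theta(a, abc)
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n_loci, size=(n_boot, n_loci))
        boot_a = a[idx].sum(axis=1)
        boot_abc = abc[idx].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            thetas = boot_a / boot_abc
        lo, hi = np.nanpercentile(thetas, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    else:
        lo = hi = float("nan")
    return FstResult(pop_a, pop_b, est, float(lo), float(hi), n_boot, n_loci)


def fst_table(results: list[FstResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pair": f"{r.pop_a}:{r.pop_b}",
                "fst": r.estimate,
                "ci_lower": r.ci_lower,
                "ci_upper": r.ci_upper,
                "n_boot": r.n_boot,
                "n_loci": r.n_loci_used,
            }
            for r in results
        ]
    )
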