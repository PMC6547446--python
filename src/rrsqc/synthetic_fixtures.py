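"""Synthetic multi-sample SNP datasets with fully known ground truth.

Two flavours:

* :func:`simulate_dataset` — a stochastic generator: Balding-Nichols
  population allele frequencies at a target F_ST, HWE genotypes within
  populations, Poisson read depths split binomially between alleles,
  technical replicates with a controlled per-call flip probability, and
  planted locus classes (sex-linked, low call rate, monomorphic, high-het,
  low-depth, allele-imbalanced). Every planted quantity lands in the truth
  ledger so pipeline estimates can be checked against it.

* :func:`fixture_suite` — tiny deterministic, hand-auditable fixtures whose
  expected values are embedded alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np

from rrsqc.genotype_store import (
    GenotypeMatrix,
    HET,
    HOM_ALT,
    HOM_REF,
    LocusRecord,
    MISSING,
    SampleSheet,
    write_vcf,
)


@dataclass
class SimConfig:
    """Knobs for :func:`simulate_dataset`; planted classes use disjoint loci."""

    n_loci: int = 1000
    samples_per_pop: tuple[int, ...] = (50, 50)
    target_fst: float = 0.10
    maf_range: tuple[float, float] = (0.10, 0.50)
    mean_depth: float = 12.0
    missing_rate: float = 0.0
    flip_prob: float = 0.0  # replicate per-call discordance
    n_replicate_pairs: int = 0
    n_sex_linked: int = 0
    n_low_call_rate: int = 0
    planted_call_rate: float = 0.20
    n_monomorphic: int = 0
    n_high_het: int = 0
    n_low_depth: int = 0
    n_imbalanced: int = 0
    imbalance_ref_prob: float = 0.95
    sex_system: str = "XY"
    locus_spacing: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("target_fst", "missing_rate", "flip_prob", "planted_call_rate",
                     "imbalance_ref_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        planted = (
            self.n_sex_linked + self.n_low_call_rate + self.n_monomorphic
            + self.n_high_het + self.n_low_depth + self.n_imbalanced
        )
        if planted > self.n_loci:
            raise ValueError(
                f"planted loci ({planted}) exceed n_loci ({self.n_loci})"
            )
        if self.n_replicate_pairs > self.samples_per_pop[0]:
            raise ValueError("more replicate pairs than samples in population 1")


@dataclass
class SimResult:
    """Generated matrix + metadata + truth ledger."""

    matrix: GenotypeMatrix
    sheet: SampleSheet
    truth: dict[str, Any] = field(default_factory=dict)

    def write(self, out_dir: str | Path, prefix: str = "sim") -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": out_dir / f"{prefix}.vcf",
            "sheet": out_dir / f"{prefix}.samples.tsv",
            "truth": out_dir / f"{prefix}.truth.json",
        }
        write_vcf(self.matrix, paths["vcf"])
        self.sheet.write(paths["sheet"])
        paths["truth"].write_text(json.dumps(self.truth, indent=2, default=_jsonable) + "\n")
        return paths


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, fst: float) -> np.ndarray:
    """Population allele frequency draw around ancestral p at divergence fst."""
    if fst < 1e-9:
        return p.copy()
    shape_a = p * (1.0 - fst) / fst
    shape_b = (1.0 - p) * (1.0 - fst) / fst
    return rng.beta(shape_a, shape_b)


def _depths_for(
    rng: np.random.Generator,
    states: np.ndarray,
    mean_depth: float,
    ref_split: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson totals split binomially for hets; homs carry one allele only."""
    total = rng.poisson(mean_depth, size=states.shape)
    dr = np.zeros(states.shape, dtype=np.int32)
    da = np.zeros(states.shape, dtype=np.int32)
    hom_ref = states == HOM_REF
    hom_alt = states == HOM_ALT
    het = states == HET
    dr[hom_ref] = total[hom_ref]
    da[hom_alt] = total[hom_alt]
    split = np.broadcast_to(ref_split[:, None], states.shape)
    het_ref = rng.binomial(total, split)
    dr[het] = het_ref[het]
    da[het] = (total - het_ref)[het]
    return dr, da


def simulate_dataset(config: SimConfig) -> SimResult:
    """Generate a synthetic multi-population SNP dataset per ``config``.

    Deterministic for a fixed seed. The truth ledger records the planted
    locus classes (by locus_id), the replicate map, and the realised values
    of every quantity a pipeline stage estimates (missing fraction,
    replicate discordance rate on comparable calls, per-population allele
    frequencies).
    """
    rng = np.random.default_rng(config.seed)
    n_pops = len(config.samples_per_pop)
    n_base = int(sum(config.samples_per_pop))
    L = config.n_loci

    # locus identities: one contig, evenly spaced beyond any thinning window
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=L)
    alt_idx = (ref_idx + rng.integers(1, 4, size=L)) % 4
    loci = [
        LocusRecord("chr1", (i + 1) * config.locus_spacing, bases[ref_idx[i]], bases[alt_idx[i]])
        for i in range(L)
    ]

    # planted class index blocks, disjoint, leading loci
    cursor = 0
    classes: dict[str, np.ndarray] = {}
    for name, count in (
        ("sex_linked", config.n_sex_linked),
        ("low_call_rate", config.n_low_call_rate),
        ("monomorphic", config.n_monomorphic),
        ("high_het", config.n_high_het),
        ("low_depth", config.n_low_depth),
        ("imbalanced", config.n_imbalanced),
    ):
        classes[name] = np.arange(cursor, cursor + count)
        cursor += count

    pop_labels = np.concatenate(
        [np.full(n, f"pop{k + 1}") for k, n in enumerate(config.samples_per_pop)]
    )
    samples = [f"s{str(i + 1).zfill(3)}" for i in range(n_base)]
    sex = np.where(np.arange(n_base) % 2 == 0, "female", "male")

    # allele frequencies: ancestral ALT freq, Balding-Nichols per population
    p_anc = rng.uniform(*config.maf_range, size=L)
    pop_freqs = np.stack(
        [_balding_nichols(rng, p_anc, config.target_fst) for _ in range(n_pops)]
    )

    states = np.empty((L, n_base), dtype=np.int8)
    col = 0
    for k, n in enumerate(config.samples_per_pop):
        states[:, col : col + n] = rng.binomial(
            2, pop_freqs[k][:, None], size=(L, n)
        ).astype(np.int8)
        col += n

    # --- planted classes overwrite the base draw -------------------------
    hetero_sex = "male" if config.sex_system == "XY" else "female"
    hetero_cols = sex == hetero_sex
    for i in classes["sex_linked"]:
        # heterogametic samples are hemizygous -> diploid-coded homozygotes
        doses = states[i, hetero_cols]
        states[i, hetero_cols] = np.where(doses >= 1, HOM_ALT, HOM_REF)
        homo = np.flatnonzero(~hetero_cols)
        if len(homo) and not (states[i, ~hetero_cols] == HET).any():
            states[i, homo[0]] = HET  # guarantee >= 1 het in homogametic sex

    for i in classes["monomorphic"]:
        states[i, :] = HOM_REF

    for i in classes["high_het"]:
        hom = rng.random(n_base) > 0.95
        states[i, :] = np.where(hom, HOM_REF, HET)

    # --- missingness ------------------------------------------------------
    if config.missing_rate > 0:
        miss = rng.random((L, n_base)) < config.missing_rate
        states[miss] = MISSING
    n_miss_planted = int(round((1.0 - config.planted_call_rate) * n_base))
    for i in classes["low_call_rate"]:
        cols_miss = rng.choice(n_base, size=n_miss_planted, replace=False)
        states[i, cols_miss] = MISSING

    # --- depths -----------------------------------------------------------
    ref_split = np.full(L, 0.5)
    ref_split[classes["imbalanced"]] = config.imbalance_ref_prob
    dr, da = _depths_for(rng, states, config.mean_depth, ref_split)
    for i in classes["low_depth"]:
        # ALT depth forced under the 2.5x carrier mean; REF stays healthy
        carriers = (states[i, :] == HET) | (states[i, :] == HOM_ALT)
        da[i, carriers] = rng.integers(0, 2, size=int(carriers.sum()))

    # --- technical replicates --------------------------------------------
    rep_groups: dict[str, str] = {}
    rep_samples: list[str] = []
    n_flips = 0
    n_rep_called = 0
    if config.n_replicate_pairs > 0:
        originals = samples[: config.n_replicate_pairs]
        rep_states = states[:, : config.n_replicate_pairs].copy()
        called = rep_states != MISSING
        flips = (rng.random(rep_states.shape) < config.flip_prob) & called
        # flip to a uniformly chosen different state
        shift = rng.integers(1, 3, size=rep_states.shape)
        rep_states[flips] = (rep_states[flips] + shift[flips]) % 3
        n_flips = int(flips.sum())
        n_rep_called = int(called.sum())
        rep_dr, rep_da = _depths_for(rng, rep_states, config.mean_depth, ref_split)
        for j, orig in enumerate(originals):
            rep_id = f"{orig}rep"
            rep_samples.append(rep_id)
            rep_groups[orig] = f"rg{j + 1}"
            rep_groups[rep_id] = f"rg{j + 1}"
        states = np.hstack([states, rep_states])
        dr = np.hstack([dr, rep_dr])
        da = np.hstack([da, rep_da])

    all_samples = samples + rep_samples
    matrix = GenotypeMatrix(loci, all_samples, states, dr, da)

    populations = {s: str(pop_labels[i]) for i, s in enumerate(samples)}
    sexes = {s: str(sex[i]) for i, s in enumerate(samples)}
    for j, rep_id in enumerate(rep_samples):
        populations[rep_id] = populations[samples[j]]
        sexes[rep_id] = sexes[samples[j]]
    sheet = SampleSheet.from_records(populations, sexes, rep_groups)

    truth: dict[str, Any] = {
        "config": asdict(config),
        "planted": {
            name: [loci[i].locus_id for i in idx] for name, idx in classes.items()
        },
        "realised_missing_fraction": float((matrix.states == MISSING).mean()),
        "realised_flip_rate": (n_flips / n_rep_called) if n_rep_called else 0.0,
        "n_replicate_flips": n_flips,
        "n_replicate_called_cells": n_rep_called,
        "ancestral_alt_freq": p_anc,
        "population_alt_freq": pop_freqs,
    }
    return SimResult(matrix, sheet, truth)


# ----------------------------------------------------------- hand fixtures

def _matrix_from_states(
    states: list[list[int]],
    samples: list[str],
    depths: tuple[list[list[int]], list[list[int]]] | None = None,
    spacing: int = 1000,
) -> GenotypeMatrix:
    n_loci = len(states)
    bases = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
    loci = [
        LocusRecord("chr1", (i + 1) * spacing, *bases[i % 4]) for i in range(n_loci)
    ]
    arr = np.array(states, dtype=np.int8)
    if depths is None:
        dr = np.where((arr == HOM_REF) | (arr == HET), 10, 0).astype(np.int32)
        da = np.where((arr == HOM_ALT) | (arr == HET), 10, 0).astype(np.int32)
    else:
        dr = np.array(depths[0], dtype=np.int32)
        da = np.array(depths[1], dtype=np.int32)
    return GenotypeMatrix(loci, samples, arr, dr, da)


def fixture_suite() -> dict[str, SimResult]:
    """Deterministic hand-auditable fixtures with expected values embedded.

    Keys: ``fst_tiny`` (2 pops x 4 samples x 2 loci worked F_ST instance),
    ``coverage_boundary`` (loci straddling the 80% coverage-diff cut-off),
    ``reproducibility_boundary`` (locus at exactly 0.85 reproducibility, one
    above, one fully concordant).
    """
    out: dict[str, SimResult] = {}

    # ---- tiny worked F_ST instance: enumerated genotypes ----------------
    samples = [f"a{i}" for i in range(1, 5)] + [f"b{i}" for i in range(1, 5)]
    states = [
        # pop a: 2,2,1,1   pop b: 0,0,0,1
        [2, 2, 1, 1, 0, 0, 0, 1],
        # pop a: 0,1,1,0   pop b: 2,2,1,2
        [0, 1, 1, 0, 2, 2, 1, 2],
    ]
    m = _matrix_from_states(states, samples)
    sheet = SampleSheet.from_records(
        {s: ("popA" if s.startswith("a") else "popB") for s in samples}
    )
    out["fst_tiny"] = SimResult(
        m, sheet, {"note": "theta fixed by independent evaluation in tests"}
    )

    # ---- coverage-difference boundary loci ------------------------------
    samples2 = ["s1", "s2"]
    states2 = [[1, 1], [1, 1], [1, 1]]
    # per-locus het depth sums: (R=5,A=2) -> 85.7% removed;
    # (R=9,A=5) -> 57.1% retained; (R=10,A=10) -> 0% retained
    dr2 = [[3, 2], [5, 4], [5, 5]]
    da2 = [[1, 1], [3, 2], [5, 5]]
    m2 = _matrix_from_states(states2, samples2, depths=(dr2, da2))
    out["coverage_boundary"] = SimResult(
        m2,
        SampleSheet.from_records({s: "pop1" for s in samples2}),
        {
            "coverage_diff_pct": [600.0 / 7.0, 400.0 / 7.0, 0.0],
            "removed_at_80": ["chr1:1000"],
        },
    )

    # ---- reproducibility boundary ---------------------------------------
    # 20 replicate pairs; locus 1: 17/20 identical = 0.85 (removed at >0.85),
    # locus 2: 18/20 = 0.90 (retained), locus 3: 20/20 = 1.0 (retained)
    n_pairs = 20
    orig = [f"r{str(i).zfill(2)}" for i in range(n_pairs)]
    reps = [o + "rep" for o in orig]
    base = [[HOM_REF] * n_pairs, [HOM_REF] * n_pairs, [HET] * n_pairs]
    dup = [row.copy() for row in base]
    for k in range(3):
        dup[0][k] = HET  # 3 discordant -> 17/20
    for k in range(2):
        dup[1][k] = HET  # 2 discordant -> 18/20
    states3 = [row + drow for row, drow in zip(base, dup)]
    m3 = _matrix_from_states(states3, orig + reps)
    groups = {s: f"rg{i + 1}" for i, s in enumerate(orig)}
    groups.update({s: f"rg{i + 1}" for i, s in enumerate(reps)})
    sheet3 = SampleSheet.from_records(
        {s: "pop1" for s in orig + reps}, replicate_groups=groups
    )
    out["reproducibility_boundary"] = SimResult(
        m3,
        sheet3,
        {
            "reproducibility": [0.85, 0.90, 1.0],
            "removed_at_0.85_strict": ["chr1:1000"],
        },
    )
    return out


def planted_failure_fixture(
    *,
    n_samples: int = 80,
    n_normal: int = 30,
    k_low_call: int = 4,
    k_low_maf: int = 3,
    k_high_het: int = 5,
    k_low_depth: int = 2,
    k_imbalanced: int = 3,
    k_sex_linked: int = 3,
) -> SimResult:
    """Deterministic fixture with disjoint planted failure classes.

    Normal loci pass every filter at the default thresholds; each planted
    class fails exactly one filter. The truth ledger carries the class
    counts and locus ids so a filter chain can be checked for exact removal.
    """
    assert n_samples % 4 == 0
    q = n_samples // 4
    samples = [f"s{str(i).zfill(3)}" for i in range(n_samples)]
    sex = {s: ("female" if i % 2 == 0 else "male") for i, s in enumerate(samples)}

    def normal_row() -> list[int]:
        # balanced mix: q hom_ref, 2q het, q hom_alt -> H_O = 0.5, MAF = 0.5
        return [HOM_REF] * q + [HET] * 2 * q + [HOM_ALT] * q

    rows: list[list[int]] = []
    classes: dict[str, list[int]] = {
        "low_call_rate": [], "low_maf": [], "high_het": [],
        "low_depth": [], "imbalanced": [], "sex_linked": [],
    }

    def add(cls: str | None, row: list[int]) -> None:
        if cls is not None:
            classes[cls].append(len(rows))
        rows.append(row)

    for _ in range(n_normal):
        add(None, normal_row())
    # low call rate: keep a balanced called subset so depth/MAF/het still pass
    keep_called = {0, 1, q, q + 1, q + 2, q + 3, 3 * q, 3 * q + 1}
    for _ in range(k_low_call):
        row = normal_row()
        for j in range(n_samples):
            if j not in keep_called:
                row[j] = MISSING  # call rate 8/n < 70%
        add("low_call_rate", row)
    # low MAF: a single het (at a male column) -> MAF = 1/(2n) < 0.01 for n=80,
    # but the locus still has ALT-carrier depth and passes the sex filter
    for _ in range(k_low_maf):
        row = [HOM_REF] * n_samples
        row[1] = HET
        add("low_maf", row)
    for _ in range(k_high_het):
        add("high_het", [HET] * n_samples)  # H_O = 1 > 0.7
    for _ in range(k_low_depth):
        add("low_depth", normal_row())
    for _ in range(k_imbalanced):
        add("imbalanced", normal_row())
    for _ in range(k_sex_linked):
        # hets only in females (XY homogametic); males homozygous
        row = [
            HET if sex[s] == "female" else (HOM_ALT if i % 4 == 1 else HOM_REF)
            for i, s in enumerate(samples)
        ]
        add("sex_linked", row)

    arr = np.array(rows, dtype=np.int8)
    dr = np.where((arr == HOM_REF) | (arr == HET), 10, 0).astype(np.int32)
    da = np.where((arr == HOM_ALT) | (arr == HET), 10, 0).astype(np.int32)
    for i in classes["low_depth"]:
        da[i, :] = np.where(arr[i, :] != HOM_REF, 1, 0)  # ALT mean 1.0 < 2.5
        dr[i, :] = np.where(arr[i, :] != HOM_ALT, 10, 0)
    for i in classes["imbalanced"]:
        het = arr[i, :] == HET
        dr[i, het] = 19
        da[i, het] = 1  # diff = 180% > 80, but ALT carrier mean >= 2.5
        da[i, arr[i, :] == HOM_ALT] = 20

    bases = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
    loci = [
        LocusRecord("chr1", (i + 1) * 1000, *bases[i % 4]) for i in range(len(rows))
    ]
    matrix = GenotypeMatrix(loci, samples, arr, dr, da)
    sheet = SampleSheet.from_records({s: "pop1" for s in samples}, sex)
    truth = {
        "n_normal": n_normal,
        "planted_counts": {k: len(v) for k, v in classes.items()},
        "planted_ids": {k: [loci[i].locus_id for i in v] for k, v in classes.items()},
    }
    return SimResult(matrix, sheet, truth)
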