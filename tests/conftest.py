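from __future__ import annotations

import numpy as np
import pytest

from rrsqc.genotype_store import GenotypeMatrix, LocusRecord, SampleSheet


def make_matrix(
    states,
    samples=None,
    depth_ref=None,
    depth_alt=None,
    spacing=1000,
    contig="chr1",
):
    """Build a matrix from a nested state list; balanced default depths."""
    states = np.array(states, dtype=np.int8)
    n_loci, n_samples = states.shape
    if samples is None:
        samples = [f"s{j + 1}" for j in range(n_samples)]
    bases = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
    loci = [
        LocusRecord(contig, (i + 1) * spacing, *bases[i % 4]) for i in range(n_loci)
    ]
    if depth_ref is None and depth_alt is None:
        depth_ref = np.where((states == 0) | (states == 1), 10, 0)
        depth_alt = np.where((states == 2) | (states == 1), 10, 0)
    return GenotypeMatrix(loci, samples, states, depth_ref, depth_alt)


def random_matrix(rng, n_loci=20, n_samples=10, missing_rate=0.1, with_depth=True):
    states = rng.integers(0, 3, size=(n_loci, n_samples)).astype(np.int8)
    states[rng.random((n_loci, n_samples)) < missing_rate] = -1
    dr = da = None
    if with_depth:
        dr = rng.integers(0, 30, size=(n_loci, n_samples)).astype(np.int32)
        da = rng.integers(0, 30, size=(n_loci, n_samples)).astype(np.int32)
    return make_matrix(states, depth_ref=dr, depth_alt=da)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_sheet():
    return SampleSheet.from_records(
        {"s1": "pop1", "s2": "pop1", "s3": "pop2", "s4": "pop2"},
        {"s1": "female", "s2": "male", "s3": "female", "s4": "male"},
    )
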