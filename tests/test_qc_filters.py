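from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import maf_oracle
from conftest import make_matrix, random_matrix
from rrsqc.genotype_store import DepthUnavailableError, GenotypeMatrix, SampleSheet
from rrsqc.qc_filters import (
    FilterConfig,
    FilterEntry,
    FilterPrerequisiteError,
    FilterReport,
    coverage_difference,
    filter_allele_depth,
    filter_call_rate,
    filter_coverage_diff,
    filter_maf,
    filter_max_het,
    filter_sex_linked,
    minor_allele_frequency,
    run_filter_chain,
    thin_one_snp_per_locus,
)
from rrsqc.synthetic_fixtures import planted_failure_fixture

states_strategy = st.lists(
    st.lists(st.sampled_from([-1, 0, 1, 2]), min_size=6, max_size=6),
    min_size=1,
    max_size=12,
)


class TestCallRate:
    def test_boundary_inclusive(self):
        # 7/10 called at threshold 0.70 -> retained
        row = [0, 1, 2, 0, 1, 2, 0, -1, -1, -1]
        m, entry = filter_call_rate(make_matrix([row]), 0.70)
        assert m.n_loci == 1 and entry.loci_removed == 0

    def test_threshold_zero_keeps_all(self, rng):
        m = random_matrix(rng, 20, 10, missing_rate=0.5)
        out, entry = filter_call_rate(m, 0.0)
        assert out.n_loci == m.n_loci

    def test_planted_low_call_rate(self):
        rows = [[0, 1, 2, 0, 1]] * 5 + [[0, -1, -1, -1, -1]] * 3
        out, entry = filter_call_rate(make_matrix(rows), 0.30)
        assert entry.loci_removed == 3
        assert out.n_loci == 5


class TestMaf:
    def test_arithmetic(self):
        row = [0] * 9 + [1]  # 1 ALT of 20 alleles -> MAF 0.05
        m = make_matrix([row])
        assert minor_allele_frequency(m)[0] == pytest.approx(0.05)
        out, _ = filter_maf(m, 0.01)
        assert out.n_loci == 1

    def test_monomorphic_removed(self):
        out, entry = filter_maf(make_matrix([[0] * 6]), 0.01)
        assert out.n_loci == 0 and entry.loci_removed == 1

    @given(states_strategy)
    @settings(max_examples=50, deadline=None)
    def test_matches_oracle(self, rows):
        m = make_matrix(rows)
        got = minor_allele_frequency(m)
        for i, row in enumerate(rows):
            expected = maf_oracle(row)
            if math.isnan(expected):
                assert math.isnan(got[i])
            else:
                assert got[i] == pytest.approx(expected)


class TestMaxHet:
    def test_removed_above(self):
        row = [1] * 8 + [0, 2]
        out, _ = filter_max_het(make_matrix([row]), 0.70)
        assert out.n_loci == 0

    def test_threshold_one_keeps_all(self):
        out, _ = filter_max_het(make_matrix([[1] * 6]), 1.0)
        assert out.n_loci == 1

    def test_boundary_inclusive(self):
        row = [1] * 7 + [0] * 3  # H_O = 0.7 exactly
        out, _ = filter_max_het(make_matrix([row]), 0.70)
        assert out.n_loci == 1


class TestAlleleDepth:
    def test_single_het(self):
        m = make_matrix(
            [[1]],
            depth_ref=np.array([[5]]),
            depth_alt=np.array([[5]]),
        )
        out, _ = filter_allele_depth(m, 2.5)
        assert out.n_loci == 1

    def test_low_alt_mean(self):
        # 3 ALT carriers at depth 2 each -> mean 2.0 < 2.5
        m = make_matrix(
            [[1, 1, 1, 0]],
            depth_ref=np.array([[10, 10, 10, 10]]),
            depth_alt=np.array([[2, 2, 2, 0]]),
        )
        out, _ = filter_allele_depth(m, 2.5)
        assert out.n_loci == 0

    def test_no_carriers_fails(self):
        out, _ = filter_allele_depth(make_matrix([[0, 0, 0]]), 2.5)
        assert out.n_loci == 0  # no ALT carriers

    def test_depth_free_refuses(self):
        m = make_matrix([[0, 1]])
        m = GenotypeMatrix(m.loci, m.samples, m.states)
        with pytest.raises(DepthUnavailableError):
            filter_allele_depth(m, 2.5)

    def test_oracle_recomputation(self, rng):
        m = random_matrix(rng, 40, 12, missing_rate=0.2)
        out, entry = filter_allele_depth(m, 2.5)
        kept = set(out.locus_ids)
        for i, loc in enumerate(m.loci):
            refs = [
                m.depth_ref[i, j]
                for j in range(m.n_samples)
                if m.states[i, j] in (0, 1)
            ]
            alts = [
                m.depth_alt[i, j]
                for j in range(m.n_samples)
                if m.states[i, j] in (1, 2)
            ]
            expect = (
                bool(refs) and bool(alts)
                and sum(refs) / len(refs) >= 2.5
                and sum(alts) / len(alts) >= 2.5
            )
            assert (loc.locus_id in kept) == expect


class TestCoverageDiff:
    def test_balanced_retained(self):
        m = make_matrix(
            [[1, 1]], depth_ref=np.array([[10, 10]]), depth_alt=np.array([[10, 10]])
        )
        assert coverage_difference(m)[0] == pytest.approx(0.0)
        out, _ = filter_coverage_diff(m, 80.0)
        assert out.n_loci == 1

    def test_hand_arithmetic_removed(self):
        # R=5, A=2 -> 100*3/3.5 = 85.71% > 80 -> removed
        m = make_matrix(
            [[1]], depth_ref=np.array([[5]]), depth_alt=np.array([[2]])
        )
        assert coverage_difference(m)[0] == pytest.approx(100 * 3 / 3.5)
        out, _ = filter_coverage_diff(m, 80.0)
        assert out.n_loci == 0

    def test_hand_arithmetic_retained(self):
        # R=9, A=5 -> 100*4/7 = 57.14% <= 80 -> retained
        m = make_matrix(
            [[1]], depth_ref=np.array([[9]]), depth_alt=np.array([[5]])
        )
        assert coverage_difference(m)[0] == pytest.approx(100 * 4 / 7)
        out, _ = filter_coverage_diff(m, 80.0)
        assert out.n_loci == 1

    def test_no_hets_pass(self):
        m = make_matrix([[0, 2, 0]])
        out, _ = filter_coverage_diff(m, 80.0)
        assert out.n_loci == 1


class TestSexLinked:
    def build(self, rows, sexes):
        m = make_matrix(rows, samples=list(sexes))
        sheet = SampleSheet.from_records({s: "p" for s in sexes}, sexes)
        return m, sheet

    def test_flagged(self):
        sexes = {"f1": "female", "f2": "female", "f3": "female",
                 "m1": "male", "m2": "male"}
        m, sheet = self.build([[1, 1, 1, 0, 2]], sexes)
        out, entry, flagged = filter_sex_linked(m, sheet, "XY")
        assert flagged == ["chr1:1000"] and out.n_loci == 0

    def test_het_male_not_flagged(self):
        sexes = {"f1": "female", "f2": "female", "m1": "male", "m2": "male"}
        m, sheet = self.build([[1, 1, 1, 0]], sexes)
        _, _, flagged = filter_sex_linked(m, sheet, "XY")
        assert flagged == []

    def test_zw_reverses_roles(self):
        sexes = {"f1": "female", "f2": "female", "m1": "male", "m2": "male"}
        m, sheet = self.build([[0, 2, 1, 1]], sexes)  # hets only in males
        _, _, flagged = filter_sex_linked(m, sheet, "ZW")
        assert flagged == ["chr1:1000"]

    def test_unknown_sex_excluded(self):
        sexes = {"f1": "female", "m1": "male", "u1": "unknown"}
        m, sheet = self.build([[1, 0, 1]], sexes)  # the only other het is unknown
        _, _, flagged = filter_sex_linked(m, sheet, "XY")
        assert flagged == ["chr1:1000"]

    def test_all_unknown_refuses(self):
        sexes = {"a": "unknown", "b": "unknown"}
        m, sheet = self.build([[1, 0]], sexes)
        with pytest.raises(FilterPrerequisiteError):
            filter_sex_linked(m, sheet, "XY")

    def test_autosomal_false_positive_rate(self):
        # HWE, MAF 0.3, n=100: P(no het among ~50 males) ~ (1-0.42)^50 << 5%
        rng = np.random.default_rng(7)
        n, L, p = 100, 1000, 0.3
        states = rng.binomial(2, p, size=(L, n)).astype(np.int8)
        samples = [f"s{i}" for i in range(n)]
        sexes = {s: ("female" if i % 2 else "male") for i, s in enumerate(samples)}
        m = make_matrix(states, samples=samples)
        sheet = SampleSheet.from_records({s: "p" for s in samples}, sexes)
        _, _, flagged = filter_sex_linked(m, sheet, "XY")
        assert len(flagged) / L < 0.05


class TestThinning:
    def test_hand_traced_chaining(self):
        m = make_matrix([[0, 1]] * 3, spacing=1)  # positions via custom loci
        from rrsqc.genotype_store import LocusRecord

        loci = [
            LocusRecord("chr1", 100, "A", "G"),
            LocusRecord("chr1", 150, "C", "T"),
            LocusRecord("chr1", 400, "G", "A"),
        ]
        m = GenotypeMatrix(loci, m.samples, m.states, m.depth_ref, m.depth_alt)
        out, entry = thin_one_snp_per_locus(m, window=77, seed=0)
        assert out.n_loci == 2
        kept = {loc.position for loc in out.loci}
        assert 400 in kept
        assert len(kept & {100, 150}) == 1

    def test_far_apart_unchanged(self, rng):
        m = random_matrix(rng, 10, 4)  # spacing 1000 >> 77
        out, _ = thin_one_snp_per_locus(m, 77, seed=1)
        assert out.n_loci == 10

    def test_deterministic(self, rng):
        m = random_matrix(rng, 30, 4)
        a, _ = thin_one_snp_per_locus(m, 5000, seed=42)
        b, _ = thin_one_snp_per_locus(m, 5000, seed=42)
        assert a.locus_ids == b.locus_ids


class TestFilterReport:
    def test_entry_consistency(self):
        with pytest.raises(ValueError):
            FilterEntry("x", {}, 10, 3, 8)

    def test_chain_enforced(self):
        report = FilterReport()
        report.add(FilterEntry("a", {}, 10, 2, 8))
        with pytest.raises(ValueError, match="chain"):
            report.add(FilterEntry("b", {}, 9, 1, 8))

    def test_serialisation(self, tmp_path):
        report = FilterReport()
        report.add(FilterEntry("a", {"t": 1}, 10, 2, 8, removed_ids=["chr1:5"]))
        report.write_tsv(tmp_path / "r.tsv")
        report.to_json(tmp_path / "r.json")
        assert (tmp_path / "r.tsv").read_text().count("\n") == 2
        assert "chr1:5" in (tmp_path / "r.json").read_text()


class TestChain:
    def test_empty_order_is_identity(self, rng):
        m = random_matrix(rng, 10, 5)
        out, report = run_filter_chain(m, None, FilterConfig(), order=[])
        assert out == m and report.entries == []

    def test_planted_classes_exact(self):
        fx = planted_failure_fixture()
        counts = fx.truth["planted_counts"]
        out, report = run_filter_chain(
            fx.matrix, fx.sheet, FilterConfig(), skip_unmet=True
        )
        by_name = {e.filter_name: e for e in report.entries}
        assert by_name["allele_depth"].loci_removed == counts["low_depth"]
        assert by_name["coverage_diff"].loci_removed == counts["imbalanced"]
        assert by_name["sex_linked"].loci_removed == counts["sex_linked"]
        assert by_name["max_obs_het"].loci_removed == counts["high_het"]
        assert by_name["call_rate"].loci_removed == counts["low_call_rate"]
        assert by_name["maf"].loci_removed == counts["low_maf"]
        assert set(by_name["maf"].removed_ids) == set(fx.truth["planted_ids"]["low_maf"])
        assert out.n_loci == fx.truth["n_normal"]

    def test_conservation(self):
        fx = planted_failure_fixture()
        _, report = run_filter_chain(fx.matrix, fx.sheet, FilterConfig(), skip_unmet=True)
        assert report.loci_in - report.total_removed == report.loci_out

    def test_failure_names_stage(self):
        fx = planted_failure_fixture()
        m = GenotypeMatrix(fx.matrix.loci, fx.matrix.samples, fx.matrix.states)
        with pytest.raises(RuntimeError, match="allele_depth"):
            run_filter_chain(m, fx.sheet, FilterConfig())


class TestFilterProperties:
    FILTERS = [
        lambda m: filter_call_rate(m, 0.6),
        lambda m: filter_maf(m, 0.05),
        lambda m: filter_max_het(m, 0.5),
        lambda m: filter_allele_depth(m, 5.0),
        lambda m: filter_coverage_diff(m, 50.0),
    ]

    @pytest.mark.parametrize("fn", FILTERS)
    def test_idempotent(self, rng, fn):
        m = random_matrix(rng, 50, 10, missing_rate=0.2)
        once, _ = fn(m)
        twice, entry = fn(once)
        assert entry.loci_removed == 0

    @pytest.mark.parametrize("fn", FILTERS)
    def test_partition_exhaustive(self, rng, fn):
        m = random_matrix(rng, 40, 8, missing_rate=0.2)
        out, entry = fn(m)
        assert set(out.locus_ids) | set(entry.removed_ids) == set(m.locus_ids)
        assert set(out.locus_ids) & set(entry.removed_ids) == set()

    def test_monotonicity_call_rate(self, rng):
        m = random_matrix(rng, 60, 10, missing_rate=0.4)
        loose, _ = filter_call_rate(m, 0.3)
        tight, _ = filter_call_rate(m, 0.7)
        assert set(tight.locus_ids) <= set(loose.locus_ids)

    def test_monotonicity_maf(self, rng):
        m = random_matrix(rng, 60, 10)
        loose, _ = filter_maf(m, 0.01)
        tight, _ = filter_maf(m, 0.2)
        assert set(tight.locus_ids) <= set(loose.locus_ids)

    def test_calls_unchanged(self, rng):
        m = random_matrix(rng, 30, 6, missing_rate=0.2)
        out, _ = filter_call_rate(m, 0.5)
        idx = {loc.locus_id: i for i, loc in enumerate(m.loci)}
        for i, loc in enumerate(out.loci):
            assert (out.states[i] == m.states[idx[loc.locus_id]]).all()


class TestFilterConfig:
    def test_defaults(self):
        cfg = FilterConfig()
        assert cfg.call_rate_min == 0.70
        assert cfg.maf_min == 0.01
        assert cfg.max_obs_het == 0.70
        assert cfg.min_mean_allele_depth == 2.5
        assert cfg.max_coverage_diff == 80.0
        assert cfg.min_reproducibility == 0.85

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"call_rate_min": 1.5},
            {"maf_min": 0.6},
            {"max_coverage_diff": 250.0},
            {"sex_system": "WZ"},
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            FilterConfig(**kwargs)
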