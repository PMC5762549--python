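"""Multiplicity-clock estimators: arm modes, counts, Case 1-5 timing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from macroevo.clock import (
    MultiplicityCounts,
    count_multiplicities,
    gain_time_summary,
    merge_arm_mode,
    time_duplication,
    time_first_nloh,
    time_gd,
)
from macroevo.core_io import ASCNSegment, SomaticSNV, toy_genome
from macroevo.simulate import GAIN, GD, UPD, EvolutionEvent, PlantedHistory, realize_profile

from conftest import make_profile


def _counts(genotype, **m):
    counts = {int(k[1:]): v for k, v in m.items()}
    return MultiplicityCounts(region=(), genotype=genotype, counts=counts)


class TestMergeArmMode:
    def test_dominant_genotype_is_mode(self, arms):
        a = arms.get("chr1q")
        segs = [
            ASCNSegment("chr1", a.start, a.start + 48_000_000, 2, 1),  # 80%
            ASCNSegment("chr1", a.start + 48_000_000, a.end, 3, 1),
        ]
        mode = merge_arm_mode(make_profile("s", segs), arms, "chr1q")
        assert mode is not None
        genotype, region = mode
        assert genotype == (2, 1)
        assert sum(s.length for s in region) == 48_000_000

    def test_even_split_has_no_mode(self, arms):
        a = arms.get("chr1q")
        mid = a.start + a.length // 2
        segs = [ASCNSegment("chr1", a.start, mid, 2, 1), ASCNSegment("chr1", mid, a.end, 1, 1)]
        assert merge_arm_mode(make_profile("s", segs), arms, "chr1q") is None

    def test_exactly_75_percent_fails_strict_rule(self, arms):
        a = arms.get("chr1q")
        cut = a.start + int(0.75 * a.length)
        segs = [ASCNSegment("chr1", a.start, cut, 2, 0), ASCNSegment("chr1", cut, a.end, 1, 1)]
        assert merge_arm_mode(make_profile("s", segs), arms, "chr1q") is None


class TestCountMultiplicities:
    def _region(self):
        return [ASCNSegment("chr1", 0, 10_000_000, 2, 0)]

    def test_counts_only_clonal_inside_region(self):
        snvs = [
            SomaticSNV("chr1", 100, "C", "T", multiplicity=2, clonal=True),
            SomaticSNV("chr1", 200, "C", "T", multiplicity=1, clonal=True),
            SomaticSNV("chr1", 300, "C", "T", multiplicity=1, clonal=False),  # subclonal
            SomaticSNV("chr2", 400, "C", "T", multiplicity=1, clonal=True),  # outside
        ]
        p = make_profile("s", self._region(), snvs=snvs)
        c = count_multiplicities(p, self._region(), (2, 0))
        assert c.counts == {2: 1, 1: 1}

    def test_multiplicity_above_major_warns_and_drops(self):
        snvs = [SomaticSNV("chr1", 100, "C", "T", multiplicity=3, clonal=True)]
        p = make_profile("s", self._region(), snvs=snvs)
        with pytest.warns(UserWarning):
            c = count_multiplicities(p, self._region(), (2, 0))
        assert c.total == 0

    def test_missing_multiplicity_raises(self):
        snvs = [SomaticSNV("chr1", 100, "C", "T", vaf=0.5)]
        p = make_profile("s", self._region(), snvs=snvs)
        with pytest.raises(ValueError, match="multiplicity"):
            count_multiplicities(p, self._region(), (2, 0))


class TestCaseFormulas:
    def test_case1_half(self):
        r = time_duplication(_counts((2, 0), m2=10, m1=20))
        assert r.case == 1 and r.t == pytest.approx(0.5)

    def test_case2_zero_when_no_doubled_mutations(self):
        r = time_duplication(_counts((2, 1), m2=0, m1=30))
        assert r.case == 2 and r.t == 0.0

    def test_case3_two_step_times(self):
        # D = M3 + M2 + (M1-M2)/3
        r = time_duplication(_counts((3, 0), m3=5, m2=5, m1=20))
        d = 5 + 5 + 15 / 3
        assert r.t == pytest.approx(5 / d)
        assert r.t2 == pytest.approx(10 / d)

    def test_case4_printed_formula(self):
        r = time_duplication(_counts((4, 0), m4=5, m2=10, m1=20))
        assert r.t == pytest.approx(1 / 3)
        assert r.t2 == pytest.approx(2 / 3)

    def test_case5_boundaries(self):
        assert time_duplication(_counts((2, 2), m2=7, m1=0)).t == 1.0
        assert time_duplication(_counts((2, 2), m2=0, m1=9)).t == 0.0

    def test_unsupported_genotype_not_applicable(self):
        r = time_duplication(_counts((5, 1), m1=10))
        assert r.label == "not_applicable" and r.t is None

    def test_zero_denominator_undefined(self):
        r = time_duplication(_counts((2, 0)))
        assert r.t is None

    def test_negative_m1_minus_m2_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipping"):
            r = time_duplication(_counts((2, 1), m2=10, m1=5))
        assert r.t == 1.0

    @given(
        m1=st.integers(0, 500), m2=st.integers(0, 500),
        m3=st.integers(0, 500), m4=st.integers(0, 500),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounds_and_case3_ordering(self, m1, m2, m3, m4):
        import warnings

        for genotype in [(2, 0), (2, 1), (3, 0), (4, 0), (2, 2)]:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                r = time_duplication(
                    MultiplicityCounts((), genotype, {1: m1, 2: m2, 3: m3, 4: m4})
                )
            if r.t is not None:
                assert 0.0 <= r.t <= 1.0
            if r.t2 is not None:
                assert r.t <= r.t2 <= 1.0

    @pytest.mark.parametrize("genotype,key", [((2, 0), 2), ((2, 1), 2), ((2, 2), 2), ((3, 0), 3), ((4, 0), 4)])
    def test_monotone_in_high_multiplicity_count(self, genotype, key):
        base = {1: 100, 2: 10, 3: 10, 4: 10}
        lo = time_duplication(MultiplicityCounts((), genotype, dict(base)))
        base[key] += 50
        hi = time_duplication(MultiplicityCounts((), genotype, base))
        assert hi.t >= lo.t


class TestProfileLevelTiming:
    def test_gd_time_recovery(self, arms):
        hist = PlantedHistory(
            "S", [EvolutionEvent(GD, 0.6)], mutation_rate=1.0, subclonal_fraction=0.05, seed=13
        )
        profile, _ = realize_profile(hist, arms)
        res = time_gd(profile, arms)
        assert res.t == pytest.approx(0.6, abs=0.05)

    def test_gd_time_requires_gd_sample(self, arms):
        p = make_profile("s", [ASCNSegment("chr1", 0, 10, 1, 1)], gd_status="NGD")
        with pytest.raises(ValueError):
            time_gd(p, arms)

    def test_first_nloh_is_minimum_over_arms(self):
        genome = toy_genome(n_chroms=2)
        hist = PlantedHistory(
            "S",
            [
                EvolutionEvent(UPD, 0.1, "chr1q", "B"),
                EvolutionEvent(UPD, 0.5, "chr2q", "B"),
            ],
            mutation_rate=8.0,
            subclonal_fraction=0.0,
            seed=2,
        )
        profile, _ = realize_profile(hist, genome)
        first, table = time_first_nloh(profile, genome)
        assert len(table) == 2
        assert first.t == pytest.approx(0.1, abs=0.05)
        assert first.t == min(r.t for r in table)

    def test_no_nloh_returns_none(self, arms):
        p = make_profile("s", [ASCNSegment("chr1", 0, 40_000_000, 1, 1)], snvs=[])
        first, table = time_first_nloh(p, arms)
        assert first is None and table == []

    def test_gain_burst_is_punctuated(self):
        genome = toy_genome(n_chroms=6)
        events = [
            EvolutionEvent(GAIN, t, f"chr{i+1}q", "A")
            for i, t in enumerate([0.05, 0.06, 0.07, 0.08])
        ]
        hist = PlantedHistory("S", events, mutation_rate=4.0, subclonal_fraction=0.0, seed=7)
        profile, _ = realize_profile(hist, genome)
        summary = gain_time_summary(profile, genome)
        assert summary["n_timed"] == 4
        assert summary["punctuated"]
        assert summary["span"] <= 0.2

    def test_spread_gains_not_punctuated(self):
        genome = toy_genome(n_chroms=6)
        events = [
            EvolutionEvent(GAIN, t, f"chr{i+1}q", "A")
            for i, t in enumerate([0.1, 0.5, 0.9])
        ]
        hist = PlantedHistory("S", events, mutation_rate=4.0, subclonal_fraction=0.0, seed=8)
        profile, _ = realize_profile(hist, genome)
        summary = gain_time_summary(profile, genome)
        assert summary["n_timed"] == 3
        assert not summary["punctuated"]

    def test_single_gain_has_zero_span(self):
        genome = toy_genome(n_chroms=2)
        hist = PlantedHistory(
            "S", [EvolutionEvent(GAIN, 0.4, "chr1q", "A")], mutation_rate=4.0,
            subclonal_fraction=0.0, seed=9,
        )
        profile, _ = realize_profile(hist, genome)
        summary = gain_time_summary(profile, genome)
        assert summary["n_timed"] == 1 and summary["span"] == 0.0
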