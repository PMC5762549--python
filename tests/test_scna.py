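"""Parity timing of focal SCNAs and the copy-number-altering score."""

import numpy as np
import pandas as pd
import pytest

from macroevo.core_io import ASCNSegment
from macroevo.scna import (
    AFTER_GD,
    BEFORE_GD,
    NOT_APPLICABLE,
    arm_modal_cn,
    classify_focal_scna,
    cn_altering_score,
    event_set_profiles,
)

from conftest import make_profile, uniform_genome


class TestArmModalCN:
    def test_majority_mode(self, arms):
        a = arms.get("chr1q")
        segs = [
            ASCNSegment("chr1", a.start, a.start + 54_000_000, 3, 1),
            ASCNSegment("chr1", a.start + 54_000_000, a.end, 3, 2),
        ]
        assert arm_modal_cn(make_profile("p", segs), arms, "chr1q") == 4

    def test_uncovered_arm_is_none(self, arms):
        assert arm_modal_cn(make_profile("p", []), arms, "chr2p") is None

    def test_tie_breaks_to_lower_cn(self, arms):
        a = arms.get("chr1q")
        mid = a.start + a.length // 2
        segs = [
            ASCNSegment("chr1", a.start, mid, 2, 1),
            ASCNSegment("chr1", mid, a.end, 1, 1),
        ]
        assert arm_modal_cn(make_profile("p", segs), arms, "chr1q") == 2


class TestParityRules:
    @pytest.mark.parametrize(
        "direction,total,minor,delta,expected",
        [
            ("deletion", 1, 0, -3, AFTER_GD),   # odd total
            ("deletion", 2, 0, -2, BEFORE_GD),  # even total, even minor
            ("deletion", 2, 1, -2, AFTER_GD),   # odd minor
            ("gain", 6, 2, 2, NOT_APPLICABLE),  # CN cap
            ("gain", 5, 1, 1, AFTER_GD),        # odd copy change
            ("gain", 4, 1, 2, BEFORE_GD),       # even copy change
        ],
    )
    def test_quoted_examples(self, direction, total, minor, delta, expected):
        assert classify_focal_scna(direction, total, minor, delta, gd=True) == expected

    def test_ngd_sample_is_not_applicable(self):
        assert classify_focal_scna("deletion", 1, 0, -1, gd=False) == NOT_APPLICABLE

    def test_total_function_below_cap(self):
        # every (direction, total, minor, delta) cell has a defined timing
        for total in range(6):
            for minor in range(total // 2 + 1):
                for delta in range(-4, 5):
                    if delta == 0:
                        continue
                    direction = "gain" if delta > 0 else "deletion"
                    out = classify_focal_scna(direction, total, minor, delta, gd=True)
                    assert out in (BEFORE_GD, AFTER_GD)


def _gene(name="G1", chrom="chr1", start=10_000_000, end=12_000_000):
    return pd.DataFrame([{"gene": name, "chrom": chrom, "start": start, "end": end}])


def _cohort_with_focal_gain(arms, n_support, n_total):
    """n_total diploid samples; n_support carry a focal +1 gain over G1."""
    profiles = []
    for i in range(n_total):
        segs = uniform_genome(arms, 1, 1)
        if i < n_support:
            segs = [s for s in segs if not (s.chrom == "chr1" and s.start == 0)]
            segs += [
                ASCNSegment("chr1", 0, 9_000_000, 1, 1),
                ASCNSegment("chr1", 9_000_000, 13_000_000, 2, 1),
                ASCNSegment("chr1", 13_000_000, 40_000_000, 1, 1),
            ]
        profiles.append(make_profile(f"s{i}", segs, gd_status="NGD"))
    return profiles


class TestScore:
    def test_threshold_inclusive_at_0_4(self, arms):
        profiles = _cohort_with_focal_gain(arms, 8, 20)
        (score,) = cn_altering_score(profiles, _gene(), arms, "gain")
        assert score.k == 8 and score.n == 20
        assert score.score == pytest.approx(0.4)
        assert score.frequent

    def test_zero_support(self, arms):
        profiles = _cohort_with_focal_gain(arms, 0, 5)
        (score,) = cn_altering_score(profiles, _gene(), arms, "gain")
        assert score.score == 0.0 and not score.frequent

    def test_unmapped_gene_skipped(self, arms):
        profiles = _cohort_with_focal_gain(arms, 1, 2)
        with pytest.warns(UserWarning):
            scores = cn_altering_score(
                profiles, _gene(chrom="chrX", start=0, end=10), arms, "gain"
            )
        assert scores == []

    def test_splitting_supporting_segment_preserves_score(self, arms):
        profiles = _cohort_with_focal_gain(arms, 3, 6)
        (before,) = cn_altering_score(profiles, _gene(), arms, "gain")
        # split each supporting segment at a point on one side of the midpoint
        for p in profiles:
            new = []
            for s in p.segments:
                if s.chrom == "chr1" and s.start == 9_000_000:
                    new.append(ASCNSegment("chr1", 9_000_000, 10_500_000, 2, 1))
                    new.append(ASCNSegment("chr1", 10_500_000, 13_000_000, 2, 1))
                else:
                    new.append(s)
            p.segments = new
        (after,) = cn_altering_score(profiles, _gene(), arms, "gain")
        assert after.k == before.k

    def test_matches_brute_force_count(self, arms):
        rng = np.random.default_rng(12)
        genes = pd.DataFrame(
            [
                {"gene": f"g{i}", "chrom": f"chr{i+1}", "start": 5_000_000 * (i + 1), "end": 5_000_000 * (i + 1) + 2_000_000}
                for i in range(5)
            ]
        )
        profiles = []
        for i in range(8):
            segs = []
            for a in (a for a in arms.arms if a.chrom in arms.autosomes):
                pos = a.start
                while pos < a.end:
                    end = min(a.end, pos + int(rng.integers(10_000_000, 40_000_000)))
                    total = int(rng.integers(1, 5))
                    minor = int(rng.integers(0, total // 2 + 1))
                    segs.append(ASCNSegment(a.chrom, pos, end, total - minor, minor))
                    pos = end
            profiles.append(make_profile(f"s{i}", segs, gd_status="NGD"))
        for direction in ("gain", "loss"):
            scores = cn_altering_score(profiles, genes, arms, direction)
            for g, s in zip(genes.itertuples(index=False), scores):
                mid = (g.start + g.end) // 2
                k = 0
                for p in profiles:
                    seg = p.segment_at(g.chrom, mid)
                    if seg is None:
                        continue
                    modal = arm_modal_cn(p, arms, arms.assign(g.chrom, mid))
                    if direction == "gain" and seg.total > modal:
                        k += 1
                    if direction == "loss" and seg.total < modal:
                        k += 1
                assert s.k == k, (direction, g.gene)


def test_event_set_tracks_recover_planted_early_deletion(arms):
    """A focal deletion planted pre-GD in every GD sample peaks in the
    before-GD track and stays flat in the after-GD track."""
    profiles = []
    for i in range(6):
        segs = uniform_genome(arms, 2, 2)  # doubled baseline
        segs = [s for s in segs if not (s.chrom == "chr9" and s.start == 0)]
        segs += [
            # pre-GD one-allele deletion at 9p21-like locus, then GD: (2,0)
            ASCNSegment("chr9", 0, 20_000_000, 2, 2),
            ASCNSegment("chr9", 20_000_000, 24_000_000, 2, 0),
            ASCNSegment("chr9", 24_000_000, 40_000_000, 2, 2),
        ]
        profiles.append(make_profile(f"s{i}", segs, gd_status="GD"))
    genes = pd.DataFrame(
        [
            {"gene": "DEL9P", "chrom": "chr9", "start": 21_000_000, "end": 23_000_000},
            {"gene": "CTRL", "chrom": "chr10", "start": 21_000_000, "end": 23_000_000},
        ]
    )
    tracks = event_set_profiles(profiles, genes, arms)
    loss = tracks[tracks.direction == "loss"].set_index("gene")
    assert loss.loc["DEL9P", "score_before_gd"] == 1.0
    assert loss.loc["DEL9P", "score_after_gd"] == 0.0
    assert loss.loc["CTRL", "score_before_gd"] == 0.0
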