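"""Multiplicity estimation, clonality, spectra, APOBEC context, GD comparison."""

import numpy as np
import pytest

from macroevo.core_io import ASCNSegment, SomaticSNV, toy_genome
from macroevo.simulate import GD, EvolutionEvent, PlantedHistory, SimConfig, realize_profile, simulate_history
from macroevo.spectrum import (
    CLASSES,
    apobec_context_fraction,
    classify_clonality,
    estimate_multiplicity,
    gd_spectrum_compare,
    gd_strata,
    multiplicity_vs_cn,
    spectrum,
    spectrum_ranksum_table,
    substitution_class,
)

from conftest import make_profile


def snv(ref="C", alt="T", vaf=None, ccf=None, mult=None, ctx=None, chrom="chr1", pos=100):
    return SomaticSNV(chrom, pos, ref, alt, vaf=vaf, ccf=ccf, multiplicity=mult, context=ctx)


class TestMultiplicityEstimator:
    @pytest.mark.parametrize(
        "vaf,purity,genotype,expected",
        [
            (0.5, 1.0, (1, 1), 1),   # heterozygous diploid
            (0.25, 0.5, (1, 1), 1),  # same site at 50% purity
            (1.0, 1.0, (2, 0), 2),   # fixed on the doubled allele
            (0.5, 1.0, (2, 2), 2),
            (0.25, 1.0, (2, 2), 1),
        ],
    )
    def test_examples(self, vaf, purity, genotype, expected):
        assert estimate_multiplicity(snv(vaf=vaf), purity, genotype) == expected

    def test_clips_into_one_to_major(self):
        assert estimate_multiplicity(snv(vaf=0.01), 1.0, (2, 1)) == 1
        assert estimate_multiplicity(snv(vaf=1.0), 1.0, (3, 2)) == 3

    def test_requires_vaf(self):
        with pytest.raises(ValueError):
            estimate_multiplicity(snv(), 1.0, (1, 1))

    def test_exact_on_noise_free_simulated_vafs(self):
        """At purity < 1 the simulator writes model-exact VAFs, so the
        estimator must recover every multiplicity with zero rounding error."""
        cfg = SimConfig(n_samples=1, mutation_rate=0.2, purity=0.6, seed=30)
        profile, _ = realize_profile(simulate_history(cfg, 0), cfg.genome)
        assert profile.purity == 0.6
        checked = 0
        for v in profile.snvs:
            if not v.clonal:
                continue
            seg = profile.segment_at(v.chrom, v.pos)
            est = estimate_multiplicity(v, profile.purity, seg.genotype)
            assert est == v.multiplicity
            checked += 1
        assert checked > 100


class TestClonality:
    def test_threshold_is_inclusive_at_0_9(self):
        assert classify_clonality(snv(ccf=1.0)) == "clonal"
        assert classify_clonality(snv(ccf=0.9)) == "clonal"
        assert classify_clonality(snv(ccf=0.5)) == "subclonal"

    def test_requires_ccf(self):
        with pytest.raises(ValueError):
            classify_clonality(snv())


class TestSpectrum:
    def test_all_ct_input(self):
        vec = spectrum([snv() for _ in range(5)])
        assert vec.proportions == (0.0, 0.0, 1.0, 0.0, 0.0, 0.0)

    def test_purine_substitutions_complemented(self):
        assert substitution_class("G", "A") == "C>T"
        assert substitution_class("A", "C") == "T>G"

    def test_empty_stratum_all_zero(self):
        assert spectrum([]).proportions == (0.0,) * 6

    def test_strand_complement_invariance(self):
        rng = np.random.default_rng(0)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        bases = "ACGT"
        snvs = []
        for _ in range(60):
            ref, alt = rng.choice(list(bases), 2, replace=False)
            snvs.append(snv(ref=str(ref), alt=str(alt)))
        flipped = [snv(ref=comp[v.ref], alt=comp[v.alt]) for v in snvs]
        assert spectrum(snvs).proportions == spectrum(flipped).proportions

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(1)
        snvs = []
        for _ in range(50):
            ref, alt = rng.choice(list("ACGT"), 2, replace=False)
            snvs.append(snv(ref=str(ref), alt=str(alt)))
        assert sum(spectrum(snvs).proportions) == pytest.approx(1.0)


class TestApobec:
    def test_all_tcw_is_one(self):
        snvs = [snv(ctx="TCA"), snv(alt="G", ctx="TCT")]
        assert apobec_context_fraction(snvs) == 1.0

    def test_no_c_mutations_is_undefined(self):
        assert apobec_context_fraction([snv(ref="T", alt="C", ctx="ATA")]) is None

    def test_purine_strand_context_flipped(self):
        # G>A at GGT is C>T at ACC on the pyrimidine strand: not TpCpW
        assert apobec_context_fraction([snv(ref="G", alt="A", ctx="GGT")]) == 0.0
        # G>A at TGA complements to TCA: TpCpW
        assert apobec_context_fraction([snv(ref="G", alt="A", ctx="TGA")]) == 1.0

    def test_matches_brute_force_counting(self):
        rng = np.random.default_rng(2)
        snvs = []
        for _ in range(200):
            ctx = "".join(rng.choice(list("ACGT"), 3))
            ctx = ctx[0] + "C" + ctx[2]
            alt = str(rng.choice(["T", "G", "A"]))
            snvs.append(snv(ref="C", alt=alt, ctx=ctx))
        keep = [v for v in snvs if v.alt in "TG"]
        expected = sum(v.context[0] == "T" and v.context[2] in "AT" for v in keep) / len(keep)
        assert apobec_context_fraction(snvs) == pytest.approx(expected)

    def test_missing_context_raises(self):
        with pytest.raises(ValueError):
            apobec_context_fraction([snv()])


class TestGDSpectrumCompare:
    def test_identical_constant_strata_give_p_one(self):
        before = np.tile([0.2, 0.1, 0.4, 0.1, 0.1, 0.1], (5, 1))
        table = spectrum_ranksum_table(before, before.copy())
        assert (table.p_value == 1.0).all()

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(3)
        n = 20
        before = rng.dirichlet([8, 1, 1, 1, 1, 1], size=n)  # C>A-heavy
        after = rng.dirichlet([1, 1, 8, 1, 1, 1], size=n)  # C>T-heavy
        table = spectrum_ranksum_table(before, after).set_index("class")
        assert table.loc["C>T", "p_value"] < 0.01
        assert table.loc["C>A", "p_value"] < 0.01

    def test_gd_strata_partition_by_multiplicity(self, arms):
        hist = PlantedHistory(
            "S", [EvolutionEvent(GD, 0.5)], mutation_rate=0.2, subclonal_fraction=0.1, seed=4
        )
        profile, _ = realize_profile(hist, arms)
        before, after = gd_strata(profile, arms)
        assert all(v.multiplicity >= 2 and v.clonal for v in before)
        assert all(v.multiplicity == 1 and v.clonal for v in after)
        assert before and after

    def test_needs_two_gd_samples(self, arms):
        with pytest.raises(ValueError):
            gd_spectrum_compare([make_profile("s", [], gd_status="GD")], arms)

    def test_similar_strata_not_flagged_on_simulated_gd_cohort(self, arms):
        cfg = SimConfig(
            n_samples=4, n_losses=0, n_gains=0, n_upds=0, n_telomere_steps=0,
            gd_probability=1.0, mutation_rate=0.3, seed=40,
        )
        profiles = []
        for i in range(cfg.n_samples):
            p, _ = realize_profile(simulate_history(cfg, i), cfg.genome)
            p.gd_status = "GD"
            profiles.append(p)
        table = gd_spectrum_compare(profiles, arms)
        # same generative spectrum before and after GD: no class survives a
        # Bonferroni correction over the six classes
        assert (table.p_value > 0.05 / 6).all()


def test_multiplicity_vs_cn_pairs():
    import pandas as pd

    segs = [ASCNSegment("chr1", 0, 10_000_000, 3, 1)]
    snvs = [snv(mult=1, pos=5_000_000), snv(mult=2, pos=6_000_000)]
    genes = pd.DataFrame([{"gene": "ONC", "chrom": "chr1", "start": 4_000_000, "end": 7_000_000}])
    df = multiplicity_vs_cn(make_profile("s", segs, snvs=snvs), genes)
    assert df.multiplicity.tolist() == [1, 2]
    assert (df.total_cn == 4).all()
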