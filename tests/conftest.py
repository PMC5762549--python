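import numpy as np
import pytest

from macroevo.core_io import ASCNSegment, GenomeArms, TumorProfile, toy_genome


@pytest.fixture(scope="session")
def arms() -> GenomeArms:
    return toy_genome()


@pytest.fixture(scope="session")
def mini_arms() -> GenomeArms:
    """Tiny genome for per-base brute-force oracles: 22 x 10 kb, cen at 4 kb."""
    return toy_genome(n_chroms=22, chrom_length=10_000, centromere=4_000)


def make_profile(sample_id, segments, gd_status=None, snvs=None, purity=1.0):
    return TumorProfile(
        sample_id=sample_id,
        purity=purity,
        gd_status=gd_status,
        segments=list(segments),
        snvs=list(snvs or []),
    )


def uniform_genome(genome: GenomeArms, major: int, minor: int) -> list[ASCNSegment]:
    """One segment per arm covering the whole autosome at one genotype."""
    return [
        ASCNSegment(a.chrom, a.start, a.end, major, minor)
        for a in genome.arms
        if a.chrom in genome.autosomes
    ]


def random_mini_segments(genome: GenomeArms, rng: np.random.Generator, max_cn=4):
    """Random full-coverage segmentation of the mini genome (for oracles)."""
    segs = []
    for arm in genome.arms:
        pos = arm.start
        while pos < arm.end:
            end = min(arm.end, pos + int(rng.integers(1_000, 6_000)))
            total = int(rng.integers(0, max_cn + 1))
            minor = int(rng.integers(0, total // 2 + 1))
            segs.append(ASCNSegment(arm.chrom, pos, end, total - minor, minor))
            pos = end
    return segs
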