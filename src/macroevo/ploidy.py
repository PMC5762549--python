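"""Whole-genome-doubling detection, GD timing by loss genotypes, and wGII.

GD detection follows the major-allele-fraction logic: a genome is called
doubled when at least half the autosome (by length) carries major allele copy
number >= 2 and that configuration is unreachable, at Monte Carlo p < 0.001,
under a null in which the sample's observed number of arm-level copy-number
events is replayed as independent single-allele arm gains on a diploid
genome.

GD timing uses only losses to two total copies: genotype 1:1 ("AB") can only
arise from losses after a doubling, while 2:0 ("AA"/"BB") marks a loss before
it; whichever genomic proportion dominates orders GD against the bulk of the
losses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import AUTOSOMES, GenomeArms, TumorProfile, split_at_centromeres

GD_FRACTION_THRESHOLD = 0.5
GD_P_THRESHOLD = 0.001
GD_N_SIMS = 100_000


@dataclass(frozen=True)
class GDCall:
    sample_id: str
    gd: bool
    major2_fraction: float
    p_value: float
    n_sims: int
    n_arm_events: int


@dataclass(frozen=True)
class GDTiming:
    sample_id: str
    length_ab: int
    length_aabb: int
    proportion_ab: float
    proportion_aa_bb: float
    difference: float
    timing_class: str  # GD_before_losses | GD_after_losses | undefined


def _arm_modal_genotype(profile: TumorProfile, arms: GenomeArms, arm_name: str):
    """Length-weighted modal (major, minor) of one arm, or None if uncovered."""
    arm = arms.get(arm_name)
    weights: dict[tuple[int, int], int] = {}
    for seg in split_at_centromeres(profile.autosomal_segments(), arms):
        if seg.chrom == arm.chrom and seg.start >= arm.start and seg.end <= arm.end:
            weights[seg.genotype] = weights.get(seg.genotype, 0) + seg.length
    if not weights:
        return None
    # ties broken toward the lower-total genotype (conservative toward NGD)
    return min(weights, key=lambda g: (-weights[g], g[0] + g[1], g))


def count_arm_events(profile: TumorProfile, arms: GenomeArms) -> int:
    """Autosomal arms whose length-weighted modal genotype deviates from 1:1."""
    n = 0
    for arm in arms.arms:
        if arm.chrom not in AUTOSOMES:
            continue
        mode = _arm_modal_genotype(profile, arms, arm.name)
        if mode is not None and mode != (1, 1):
            n += 1
    return n


def major2_fraction(profile: TumorProfile, arms: GenomeArms) -> float:
    """Length fraction of the covered autosome with major copy number >= 2."""
    covered = 0
    hit = 0
    for seg in profile.autosomal_segments():
        covered += seg.length
        if seg.major >= 2:
            hit += seg.length
    if covered == 0:
        raise ValueError(f"{profile.sample_id}: no autosomal coverage")
    return hit / covered


def detect_gd(
    profile: TumorProfile,
    arms: GenomeArms,
    n_sims: int = GD_N_SIMS,
    seed: int | np.random.Generator = 0,
) -> GDCall:
    """Call whole-genome doubling for one sample.

    The null replays ``count_arm_events(profile)`` independent single-allele
    arm gains on a diploid genome; the simulated major>=2 fraction is then
    the total length of arms hit at least once. p is the add-one Monte Carlo
    estimate of P(simulated fraction >= observed fraction).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frac = major2_fraction(profile, arms)
    n_events = count_arm_events(profile, arms)

    auto_arms = [a for a in arms.arms if a.chrom in AUTOSOMES]
    lengths = np.array([a.length for a in auto_arms], dtype=float)
    total = lengths.sum()
    if n_events == 0:
        p = 1.0
    else:
        draws = rng.integers(0, len(auto_arms), size=(n_sims, n_events))
        hit = np.zeros((n_sims, len(auto_arms)), dtype=bool)
        rows = np.repeat(np.arange(n_sims), n_events)
        hit[rows, draws.ravel()] = True
        sim_frac = hit @ lengths / total
        p = (1 + int((sim_frac >= frac - 1e-12).sum())) / (n_sims + 1)

    gd = frac >= GD_FRACTION_THRESHOLD and p < GD_P_THRESHOLD
    return GDCall(profile.sample_id, bool(gd), float(frac), float(p), n_sims, n_events)


def gd_timing_by_losses(profile: TumorProfile) -> GDTiming:
    """Order GD against copy-number losses from total-copy-2 genotypes.

    Only autosomal segments with total copy number 2 qualify: 1:1 is "AB"
    (loss after GD), 2:0 is "AA"/"BB" (loss before GD). A higher AB
    proportion classifies GD before the majority of losses, and vice versa.
    """
    if profile.gd_status != "GD":
        raise ValueError(
            f"{profile.sample_id}: GD timing by losses requires a GD sample"
        )
    len_ab = sum(
        s.length for s in profile.autosomal_segments() if s.genotype == (1, 1)
    )
    len_aabb = sum(
        s.length for s in profile.autosomal_segments() if s.genotype == (2, 0)
    )
    qualifying = len_ab + len_aabb
    if qualifying == 0:
        return GDTiming(profile.sample_id, 0, 0, 0.0, 0.0, 0.0, "undefined")
    p_ab = len_ab / qualifying
    p_aabb = len_aabb / qualifying
    diff = p_ab - p_aabb
    if diff > 0:
        cls = "GD_before_losses"
    elif diff < 0:
        cls = "GD_after_losses"
    else:
        cls = "undefined"
    return GDTiming(profile.sample_id, len_ab, len_aabb, p_ab, p_aabb, diff, cls)


def wgii(profile: TumorProfile) -> float:
    """Weighted genome instability index.

    Per autosome, the length fraction whose total copy number differs from
    the sample's length-weighted modal total CN; wGII is the unweighted mean
    over covered autosomes (uncovered chromosomes are excluded).
    """
    segs = profile.autosomal_segments()
    if not segs:
        raise ValueError(f"{profile.sample_id}: no autosomal coverage")
    weights: dict[int, int] = {}
    for s in segs:
        weights[s.total] = weights.get(s.total, 0) + s.length
    modal = min(weights, key=lambda cn: (-weights[cn], cn))  # tie -> lower CN

    fractions = []
    for chrom in AUTOSOMES:
        chrom_segs = [s for s in segs if s.chrom == chrom]
        if not chrom_segs:
            continue
        covered = sum(s.length for s in chrom_segs)
        aberrant = sum(s.length for s in chrom_segs if s.total != modal)
        fractions.append(aberrant / covered)
    return float(np.mean(fractions))
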