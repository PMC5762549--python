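"""Molecular-time estimation of duplications from clonal SNV multiplicities.

Under a Poisson mutation clock, a mutation that predates a duplication rides
along on every copy descended from its lineage, so its multiplicity exceeds
one, while mutations after the last duplication have multiplicity one.
Equating observed multiplicity-class counts M_P (clonal SNVs at multiplicity
P in a region) with their lineage-model expectations yields closed-form
estimators for the duplication time T on the molecular-time scale in [0, 1]:

  (2,0)  one loss then one duplication:       T = M2 / (M2 + M1/2)
  (2,1)  one duplication, other allele kept:  T = M2 / (M2 + (M1-M2)/3)
  (3,0)  loss then two sequential dups:       D = M3 + M2 + (M1-M2)/3,
                                              T1 = M3/D, T2 = (M3+M2)/D
  (4,0)  loss then two rounds of doubling:    D = M4 + M2/2 + M1/4,
                                              T1 = M4/D, T2 = (M4+M2/2)/D
  (2,2)  whole-genome doubling:               T = (M2/2) / (M2/2 + M1/4)

A region is timeable only when one genotype occupies more than 75% of its
arm (the arm's mode). Sampling noise can make M1 < M2 in the (2,1)/(3,0)
denominators; the negative term is clipped to zero with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_io import AUTOSOMES, ASCNSegment, GenomeArms, SomaticSNV, TumorProfile, split_at_centromeres

MODE_FRACTION = 0.75  # strict: mode must exceed 0.75 of covered arm length

CASE_OF_GENOTYPE = {(2, 0): 1, (2, 1): 2, (3, 0): 3, (4, 0): 4, (2, 2): 5}
TIMEABLE_GENOTYPES = tuple(CASE_OF_GENOTYPE)


@dataclass(frozen=True)
class MultiplicityCounts:
    region: tuple[tuple[str, int, int], ...]  # (chrom, start, end) intervals
    genotype: tuple[int, int]
    counts: dict[int, int] = field(default_factory=dict)

    def m(self, p: int) -> int:
        return self.counts.get(p, 0)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class TimingResult:
    region: tuple[tuple[str, int, int], ...]
    label: str  # gain | NLOH | GD | ...
    genotype: tuple[int, int]
    case: int
    t: float | None
    t2: float | None = None
    counts: dict[int, int] = field(default_factory=dict)


def merge_arm_mode(
    profile: TumorProfile, arms: GenomeArms, arm_name: str
) -> tuple[tuple[int, int], list[ASCNSegment]] | None:
    """The arm's modal genotype and its merged segments, or None when no
    genotype exceeds 75% of the covered arm length."""
    arm = arms.get(arm_name)
    segs = [
        s
        for s in split_at_centromeres(profile.segments, arms)
        if s.chrom == arm.chrom and arm.start <= s.start and s.end <= arm.end
    ]
    covered = sum(s.length for s in segs)
    if covered == 0:
        return None
    weights: dict[tuple[int, int], int] = {}
    for s in segs:
        weights[s.genotype] = weights.get(s.genotype, 0) + s.length
    genotype, weight = max(weights.items(), key=lambda kv: (kv[1], kv[0]))
    if weight / covered <= MODE_FRACTION:
        return None
    return genotype, [s for s in segs if s.genotype == genotype]


def count_multiplicities(
    profile: TumorProfile,
    region: list[ASCNSegment],
    genotype: tuple[int, int],
) -> MultiplicityCounts:
    """Clonal-SNV multiplicity class counts inside a merged region.

    Subclonal SNVs are excluded; multiplicities above the genotype's major
    copy number are dropped with a warning (inconsistent with the genotype).
    """
    counts: dict[int, int] = {}
    major = genotype[0]
    n_over = 0
    for snv in profile.snvs:
        if not any(
            s.chrom == snv.chrom and s.contains(snv.pos) for s in region
        ):
            continue
        if snv.multiplicity is None or snv.clonal is None:
            raise ValueError(
                f"{profile.sample_id}: SNV {snv.chrom}:{snv.pos} lacks "
                "multiplicity/clonality; run estimate_multiplicity and "
                "classify_clonality first"
            )
        if not snv.clonal:
            continue
        if snv.multiplicity > major:
            n_over += 1
            continue
        counts[snv.multiplicity] = counts.get(snv.multiplicity, 0) + 1
    if n_over:
        warnings.warn(
            f"{profile.sample_id}: {n_over} clonal SNV(s) with multiplicity "
            f"above major CN {major} excluded"
        )
    return MultiplicityCounts(
        region=tuple((s.chrom, s.start, s.end) for s in region),
        genotype=genotype,
        counts=counts,
    )


def _clip01(x: float) -> float:
    return float(min(1.0, max(0.0, x)))


def _pos_diff(m1: int, m2: int) -> float:
    if m1 < m2:
        warnings.warn(f"M1 ({m1}) < M2 ({m2}); clipping M1-M2 to 0 (sampling noise)")
        return 0.0
    return float(m1 - m2)


def time_duplication(counts: MultiplicityCounts, label: str = "gain") -> TimingResult:
    """Apply the case formula matching the region's genotype.

    Returns t=None (undefined) on a zero denominator; genotypes outside the
    five cases yield label ``not_applicable``.
    """
    g = counts.genotype
    if g not in CASE_OF_GENOTYPE:
        return TimingResult(counts.region, "not_applicable", g, 0, None, counts=counts.counts)
    case = CASE_OF_GENOTYPE[g]
    m1, m2, m3, m4 = counts.m(1), counts.m(2), counts.m(3), counts.m(4)
    t = t2 = None
    if case == 1:
        d = m2 + m1 / 2.0
        if d > 0:
            t = _clip01(m2 / d)
    elif case == 2:
        d = m2 + _pos_diff(m1, m2) / 3.0
        if d > 0:
            t = _clip01(m2 / d)
    elif case == 3:
        d = m3 + m2 + _pos_diff(m1, m2) / 3.0
        if d > 0:
            t = _clip01(m3 / d)
            t2 = _clip01((m3 + m2) / d)
    elif case == 4:
        d = m4 + m2 / 2.0 + m1 / 4.0
        if d > 0:
            t = _clip01(m4 / d)
            t2 = _clip01((m4 + m2 / 2.0) / d)
    elif case == 5:
        d = m2 / 2.0 + m1 / 4.0
        if d > 0:
            t = _clip01((m2 / 2.0) / d)
    return TimingResult(counts.region, label, g, case, t, t2, counts.counts)


def time_gd(
    profile: TumorProfile, arms: GenomeArms, per_arm: bool = False
) -> TimingResult | list[TimingResult]:
    """Molecular time of the genome doubling from 2:2-genotype regions.

    Default pools clonal M1/M2 over every arm whose mode is 2:2 and applies
    the GD case once genome-wide; ``per_arm=True`` returns one estimate per
    qualifying arm instead.
    """
    if profile.gd_status != "GD":
        raise ValueError(f"{profile.sample_id}: GD timing requires a GD sample")
    per_arm_counts = []
    for arm in arms.arms:
        if arm.chrom not in AUTOSOMES:
            continue
        mode = merge_arm_mode(profile, arms, arm.name)
        if mode is None or mode[0] != (2, 2):
            continue
        per_arm_counts.append(count_multiplicities(profile, mode[1], (2, 2)))
    if per_arm:
        return [time_duplication(c, label="GD") for c in per_arm_counts]
    if not per_arm_counts:
        return TimingResult((), "GD", (2, 2), 5, None)
    pooled: dict[int, int] = {}
    region: list = []
    for c in per_arm_counts:
        region.extend(c.region)
        for p, n in c.counts.items():
            pooled[p] = pooled.get(p, 0) + n
    return time_duplication(
        MultiplicityCounts(tuple(region), (2, 2), pooled), label="GD"
    )


def time_first_nloh(
    profile: TumorProfile, arms: GenomeArms
) -> tuple[TimingResult | None, list[TimingResult]]:
    """Time every NLOH arm (mode 2:0, Case 1) and return the earliest."""
    results = []
    for arm in arms.arms:
        if arm.chrom not in AUTOSOMES:
            continue
        mode = merge_arm_mode(profile, arms, arm.name)
        if mode is None or mode[0] != (2, 0):
            continue
        counts = count_multiplicities(profile, mode[1], (2, 0))
        res = time_duplication(counts, label="NLOH")
        if res.t is not None:
            results.append(res)
    if not results:
        return None, []
    return min(results, key=lambda r: r.t), results


def gain_time_summary(profile: TumorProfile, arms: GenomeArms) -> dict:
    """Per-arm duplication times plus a dispersion summary.

    Times every arm whose mode is a timeable gained genotype; the
    ``punctuated`` flag (span <= 0.2 over >= 3 timed gains) is a documented
    heuristic for burst-like karyotype evolution, not a literature rule.
    """
    per_arm = []
    for arm in arms.arms:
        if arm.chrom not in AUTOSOMES:
            continue
        mode = merge_arm_mode(profile, arms, arm.name)
        if mode is None:
            continue
        genotype = mode[0]
        if genotype not in TIMEABLE_GENOTYPES or genotype == (2, 0):
            continue  # (2,0) is an NLOH, not a gain
        counts = count_multiplicities(profile, mode[1], genotype)
        res = time_duplication(counts, label="gain")
        if res.t is not None:
            per_arm.append({"arm": arm.name, "genotype": genotype, "t": res.t, "t2": res.t2})
    times = [r["t"] for r in per_arm]
    summary = {
        "sample": profile.sample_id,
        "n_timed": len(times),
        "min": float(np.min(times)) if times else None,
        "median": float(np.median(times)) if times else None,
        "max": float(np.max(times)) if times else None,
        "span": float(np.max(times) - np.min(times)) if times else None,
        "punctuated": bool(times and len(times) >= 3 and (max(times) - min(times)) <= 0.2),
        "per_arm": per_arm,
    }
    return summary
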