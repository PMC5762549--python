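"""Loss-of-heterozygosity detection, NLOH mechanism partition, arm-level LOH.

Any segment with minor copy number 0 is an LOH event, categorized by its
genotype: 0:0 homozygous deletion, 1:0 deletion-LOH, 2:0 copy-neutral LOH
(NLOH), >=3:0 amplified LOH. In a genome-doubled sample, a 2:0 genotype is
exactly what one pre-GD single-allele loss followed by the doubling produces
(GD-derived); higher even LOH states (4:0, ...) require a copy-neutral
mechanism such as uniparental disomy before the doubling, and odd-major
states cannot come from a single loss plus GD at all, so both are labelled
intrinsic. In a non-doubled sample every NLOH is intrinsic by definition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .core_io import (
    AUTOSOMES,
    ASCNSegment,
    GenomeArms,
    TumorProfile,
    assign_arm,
    split_at_centromeres,
)

ARM_LEVEL_FRACTION = 0.75  # strict: length > 0.75 x arm length

HOMOZYGOUS_DELETION = "homozygous_deletion"
DELETION_LOH = "deletion_LOH"
NLOH = "NLOH"
AMPLIFIED_LOH = "amplified_LOH"

GD_DERIVED = "GD_derived"
INTRINSIC = "intrinsic"

CATEGORIES = (HOMOZYGOUS_DELETION, DELETION_LOH, NLOH, AMPLIFIED_LOH)


@dataclass(frozen=True)
class LOHEvent:
    sample_id: str
    chrom: str
    start: int
    end: int
    major: int
    category: str
    arm: str
    arm_level: bool
    mechanism: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


def categorize(major: int, minor: int) -> str | None:
    """LOH category of a genotype, or None when heterozygosity is retained."""
    if minor != 0:
        return None
    if major == 0:
        return HOMOZYGOUS_DELETION
    if major == 1:
        return DELETION_LOH
    if major == 2:
        return NLOH
    return AMPLIFIED_LOH


def detect_loh(profile: TumorProfile, arms: GenomeArms) -> list[LOHEvent]:
    """All LOH events of a sample, with adjacent same-genotype segments on
    one arm merged and the arm-level flag set (length > 0.75 x arm length)."""
    segs = split_at_centromeres(profile.autosomal_segments(), arms)
    loh_segs = [s for s in segs if s.minor == 0]
    # merge contiguous same-genotype runs within an arm
    merged: list[ASCNSegment] = []
    for seg in sorted(loh_segs, key=lambda s: (s.chrom, s.start)):
        if (
            merged
            and merged[-1].chrom == seg.chrom
            and merged[-1].end == seg.start
            and merged[-1].genotype == seg.genotype
            and assign_arm(merged[-1], arms) == assign_arm(seg, arms)
        ):
            merged[-1] = replace(merged[-1], end=seg.end)
        else:
            merged.append(seg)

    events = []
    for seg in merged:
        arm_name = assign_arm(seg, arms)
        arm = arms.get(arm_name)
        events.append(
            LOHEvent(
                sample_id=profile.sample_id,
                chrom=seg.chrom,
                start=seg.start,
                end=seg.end,
                major=seg.major,
                category=categorize(seg.major, 0),
                arm=arm_name,
                arm_level=seg.length > ARM_LEVEL_FRACTION * arm.length,
            )
        )
    return events


def partition_nloh(events: list[LOHEvent], gd: bool | None) -> list[LOHEvent]:
    """Set the mechanism of every NLOH / amplified-LOH event."""
    if gd is None:
        raise ValueError("GD status must be known to partition NLOH events")
    out = []
    for e in events:
        if e.category not in (NLOH, AMPLIFIED_LOH):
            out.append(e)
        elif not gd:
            out.append(replace(e, mechanism=INTRINSIC))
        elif e.major == 2:
            out.append(replace(e, mechanism=GD_DERIVED))
        else:
            out.append(replace(e, mechanism=INTRINSIC))
    return out


def arm_loh_proportions(cohort_events: list[list[LOHEvent]], arms: GenomeArms):
    """Per-arm fraction of samples carrying >=1 arm-level event, by category.

    Takes one event list per sample; returns a DataFrame ordered by total
    proportion descending.
    """
    import pandas as pd

    n = len(cohort_events)
    arm_names = [a.name for a in arms.arms if a.chrom in AUTOSOMES]
    counts = {arm: {c: 0 for c in CATEGORIES} for arm in arm_names}
    for events in cohort_events:
        seen: set[tuple[str, str]] = set()
        for e in events:
            if e.arm_level and e.arm in counts and (e.arm, e.category) not in seen:
                counts[e.arm][e.category] += 1
                seen.add((e.arm, e.category))
    rows = []
    for arm in arm_names:
        row = {"arm": arm}
        for c in CATEGORIES:
            row[c] = counts[arm][c] / n if n else 0.0
        row["total"] = sum(row[c] for c in CATEGORIES)
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values("total", ascending=False, kind="stable").reset_index(drop=True)


def genome_fraction_by_mechanism(
    events: list[LOHEvent], profile: TumorProfile
) -> tuple[float, float]:
    """(GD-derived fraction, intrinsic fraction) of the covered autosome
    occupied by NLOH / amplified-LOH."""
    covered = sum(s.length for s in profile.autosomal_segments())
    if covered == 0:
        return (0.0, 0.0)
    gd_len = sum(e.length for e in events if e.mechanism == GD_DERIVED)
    in_len = sum(e.length for e in events if e.mechanism == INTRINSIC)
    return (gd_len / covered, in_len / covered)


def nloh_counts(events: list[LOHEvent]) -> dict[str, float]:
    """Intrinsic-NLOH burden by both conventions: event count and length."""
    nloh_like = [e for e in events if e.category in (NLOH, AMPLIFIED_LOH)]
    intrinsic = [e for e in nloh_like if e.mechanism == INTRINSIC]
    total_len = sum(e.length for e in nloh_like)
    return {
        "n_nloh_events": len(nloh_like),
        "n_intrinsic_events": len(intrinsic),
        "intrinsic_event_fraction": len(intrinsic) / len(nloh_like) if nloh_like else 0.0,
        "intrinsic_length_fraction": (
            sum(e.length for e in intrinsic) / total_len if total_len else 0.0
        ),
    }
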