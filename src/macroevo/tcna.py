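"""Telomere-bounded copy-number alterations (TCNAs).

An arm's copy-number profile, read from the centromere out to the telomere,
is deconstructed into unit amplification/deletion steps each extending from
an internal breakpoint to the telomeric end: a CN change of +-k at a segment
boundary emits k unit events of that sign. The signed event sum therefore
always equals telomere CN minus centromere CN, and the event count equals
the total variation of the CN walk — the minimum number of telomere-anchored
unit steps reproducing the profile from the centromeric baseline.

Coverage gaps between centromere and telomere are hard boundaries: each
covered block is deconstructed on its own and all events on a gapped arm are
flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core_io import ASCNSegment, GenomeArms, TumorProfile, split_at_centromeres

AMPLIFICATION = "amplification"
DELETION = "deletion"
NONE = "none"


@dataclass(frozen=True)
class ArmProfile:
    """Ordered total-CN walk of one arm, centromere -> telomere."""

    arm: str
    telomere_is_start: bool
    segments: tuple[ASCNSegment, ...]  # ordered centromere -> telomere
    arm_start: int
    arm_end: int

    @property
    def centromere_cn(self) -> int | None:
        return self.segments[0].total if self.segments else None

    @property
    def telomere_cn(self) -> int | None:
        return self.segments[-1].total if self.segments else None

    @property
    def covers_centromere_end(self) -> bool:
        if not self.segments:
            return False
        s = self.segments[0]
        return s.end == self.arm_end if self.telomere_is_start else s.start == self.arm_start

    @property
    def covers_telomere_end(self) -> bool:
        if not self.segments:
            return False
        s = self.segments[-1]
        return s.start == self.arm_start if self.telomere_is_start else s.end == self.arm_end

    @property
    def gapped(self) -> bool:
        for a, b in zip(self.segments, self.segments[1:]):
            boundary = a.start if self.telomere_is_start else a.end
            nxt = b.end if self.telomere_is_start else b.start
            if boundary != nxt:
                return True
        return False


@dataclass(frozen=True)
class TCNAEvent:
    arm: str
    sign: int  # +1 amplification, -1 deletion
    breakpoint: int  # the interval from here to the telomere is altered
    gapped: bool = False


def arm_profile(profile: TumorProfile, arms: GenomeArms, arm_name: str) -> ArmProfile:
    arm = arms.get(arm_name)
    segs = [
        s
        for s in split_at_centromeres(profile.segments, arms)
        if s.chrom == arm.chrom and arm.start <= s.start and s.end <= arm.end
    ]
    segs.sort(key=lambda s: s.start, reverse=arm.telomere_is_start)
    return ArmProfile(arm_name, arm.telomere_is_start, tuple(segs), arm.start, arm.end)


def detect_tcna(ap: ArmProfile) -> str | None:
    """Amplification/deletion/none by telomere-adjacent vs centromere-adjacent
    total CN; None (undefined) when either arm end is uncovered."""
    if not (ap.covers_centromere_end and ap.covers_telomere_end):
        return None
    if ap.telomere_cn > ap.centromere_cn:
        return AMPLIFICATION
    if ap.telomere_cn < ap.centromere_cn:
        return DELETION
    return NONE


def deconstruct_arm(ap: ArmProfile) -> list[TCNAEvent]:
    """Unit telomere-bounded steps reproducing the arm's CN walk."""
    events: list[TCNAEvent] = []
    gapped = ap.gapped
    for a, b in zip(ap.segments, ap.segments[1:]):
        contiguous = (
            b.end == a.start if ap.telomere_is_start else b.start == a.end
        )
        if not contiguous:
            continue  # hard boundary; the next block restarts its own baseline
        delta = b.total - a.total
        breakpoint = a.start if ap.telomere_is_start else a.end
        sign = 1 if delta > 0 else -1
        for _ in range(abs(delta)):
            events.append(TCNAEvent(ap.arm, sign, breakpoint, gapped))
    return events


def apply_events(ap: ArmProfile, events: list[TCNAEvent]) -> list[int]:
    """Re-apply unit events to the centromeric baseline; returns the total CN
    of each segment (centromere -> telomere order). Round-trip check."""
    totals = []
    for seg in ap.segments:
        cn = ap.centromere_cn
        for e in events:
            telomeric = (
                seg.end <= e.breakpoint if ap.telomere_is_start else seg.start >= e.breakpoint
            )
            if telomeric:
                cn += e.sign
        totals.append(cn)
    return totals


def gene_tcna_flag(
    profile: TumorProfile, arms: GenomeArms, chrom: str, midpoint: int
) -> bool:
    """True iff the gene midpoint lies inside the telomere-reaching interval
    of at least one amplification event on its arm."""
    arm_name = arms.assign(chrom, midpoint)
    if arm_name == "unmapped":
        raise ValueError(f"gene midpoint {chrom}:{midpoint} outside the arm map")
    ap = arm_profile(profile, arms, arm_name)
    for e in deconstruct_arm(ap):
        if e.sign != 1:
            continue
        inside = midpoint < e.breakpoint if ap.telomere_is_start else midpoint >= e.breakpoint
        if inside:
            return True
    return False


def tcna_summary(
    profiles: list[TumorProfile], arms: GenomeArms
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(per-sample counts, per-arm amp/del counts, all events) for a cohort."""
    per_sample, per_arm_rows, event_rows = [], [], []
    arm_names = [a.name for a in arms.arms]
    arm_counts = {arm: {"amplification": 0, "deletion": 0} for arm in arm_names}
    for p in profiles:
        n_amp = n_del = 0
        for arm in arm_names:
            ap = arm_profile(p, arms, arm)
            for e in deconstruct_arm(ap):
                event_rows.append(
                    {
                        "sample": p.sample_id,
                        "arm": arm,
                        "sign": e.sign,
                        "breakpoint": e.breakpoint,
                        "gapped": e.gapped,
                    }
                )
                if e.sign > 0:
                    n_amp += 1
                    arm_counts[arm]["amplification"] += 1
                else:
                    n_del += 1
                    arm_counts[arm]["deletion"] += 1
        per_sample.append(
            {"sample": p.sample_id, "n_amplification": n_amp, "n_deletion": n_del, "n_tcna": n_amp + n_del}
        )
    for arm in arm_names:
        per_arm_rows.append({"arm": arm, **arm_counts[arm]})
    return (
        pd.DataFrame(per_sample, columns=["sample", "n_amplification", "n_deletion", "n_tcna"]),
        pd.DataFrame(per_arm_rows, columns=["arm", "amplification", "deletion"]),
        pd.DataFrame(event_rows, columns=["sample", "arm", "sign", "breakpoint", "gapped"]),
    )
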