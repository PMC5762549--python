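"""Focal SCNA timing relative to GD and the per-gene copy-number-altering score.

Parity rules (applied to genome-doubled samples, total copy number < 6):
deletions with an odd total copy number or an odd minor copy number must
postdate the doubling (an even pre-GD loss is doubled into even numbers),
other deletions predate it; gains with an even copy change relative to the
arm's modal copy number predate GD (the change itself was doubled), gains
with an odd change postdate it.

The copy-number-altering score of a gene is k/n: the fraction of cohort
samples harboring a segment that spans the gene's midpoint and deviates from
its arm's modal total copy number in the stated direction. A score >= 0.4
flags a frequently altered gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .core_io import GenomeArms, TumorProfile, split_at_centromeres

FOCAL_CN_CAP = 6
FOCAL_ARM_FRACTION = 0.75
SCORE_THRESHOLD = 0.4

BEFORE_GD = "before_GD"
AFTER_GD = "after_GD"
NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class FocalSCNA:
    chrom: str
    start: int
    end: int
    total: int
    minor: int
    arm_modal_cn: int
    direction: str  # "gain" | "deletion"
    delta: int  # segment total - arm modal total
    timing: str


@dataclass(frozen=True)
class GeneScore:
    gene: str
    chrom: str
    midpoint: int
    direction: str
    k: int
    n: int

    @property
    def score(self) -> float:
        return self.k / self.n if self.n else 0.0

    @property
    def frequent(self) -> bool:
        return self.score >= SCORE_THRESHOLD


def arm_modal_cn(profile: TumorProfile, arms: GenomeArms, arm_name: str) -> int | None:
    """Length-weighted modal total CN of an arm; ties break to the lower CN.
    None when the arm is uncovered."""
    arm = arms.get(arm_name)
    weights: dict[int, int] = {}
    for seg in split_at_centromeres(profile.segments, arms):
        if seg.chrom == arm.chrom and arm.start <= seg.start and seg.end <= arm.end:
            weights[seg.total] = weights.get(seg.total, 0) + seg.length
    if not weights:
        return None
    return min(weights, key=lambda cn: (-weights[cn], cn))


def classify_focal_scna(
    direction: str, total: int, minor: int, delta: int, gd: bool
) -> str:
    """Pre-/post-GD parity classification of one focal SCNA."""
    if not gd or total >= FOCAL_CN_CAP:
        return NOT_APPLICABLE
    if direction == "deletion":
        return AFTER_GD if (total % 2 == 1 or minor % 2 == 1) else BEFORE_GD
    if direction == "gain":
        return BEFORE_GD if delta % 2 == 0 else AFTER_GD
    raise ValueError(f"unknown direction {direction!r}")


def focal_scnas(profile: TumorProfile, arms: GenomeArms) -> list[FocalSCNA]:
    """All focal (< 75% of arm length) deviations from the arm modal CN,
    with parity timing for GD samples."""
    gd = profile.gd_status == "GD"
    out: list[FocalSCNA] = []
    modal_cache: dict[str, int | None] = {}
    for seg in split_at_centromeres(profile.segments, arms):
        arm_name = arms.assign(seg.chrom, seg.start)
        if arm_name == "unmapped":
            continue
        arm = arms.get(arm_name)
        if seg.length >= FOCAL_ARM_FRACTION * arm.length:
            continue
        if arm_name not in modal_cache:
            modal_cache[arm_name] = arm_modal_cn(profile, arms, arm_name)
        modal = modal_cache[arm_name]
        if modal is None:
            continue
        delta = seg.total - modal
        if delta == 0:
            continue
        direction = "gain" if delta > 0 else "deletion"
        timing = classify_focal_scna(direction, seg.total, seg.minor, delta, gd)
        out.append(
            FocalSCNA(
                seg.chrom, seg.start, seg.end, seg.total, seg.minor,
                modal, direction, delta, timing,
            )
        )
    return out


def _supports(
    profile: TumorProfile,
    arms: GenomeArms,
    chrom: str,
    midpoint: int,
    direction: str,
    timing_filter: str | None,
) -> bool:
    """Does this sample support the gene: a single segment spans the gene's
    midpoint and deviates from its arm modal CN in the given direction (and,
    when a timing filter is set, the segment is focal with matching parity
    timing)."""
    for seg in split_at_centromeres(profile.segments, arms):
        if seg.chrom != chrom or not seg.contains(midpoint):
            continue
        arm_name = arms.assign(chrom, midpoint)
        if arm_name == "unmapped":
            return False
        modal = arm_modal_cn(profile, arms, arm_name)
        if modal is None:
            return False
        delta = seg.total - modal
        if direction == "gain" and delta <= 0:
            return False
        if direction == "loss" and delta >= 0:
            return False
        if timing_filter is not None:
            arm = arms.get(arm_name)
            if seg.length >= FOCAL_ARM_FRACTION * arm.length:
                return False
            timing = classify_focal_scna(
                "gain" if delta > 0 else "deletion",
                seg.total,
                seg.minor,
                delta,
                profile.gd_status == "GD",
            )
            return timing == timing_filter
        return True
    return False


def cn_altering_score(
    profiles: list[TumorProfile],
    genes: pd.DataFrame,
    arms: GenomeArms,
    direction: str,
    timing_filter: str | None = None,
) -> list[GeneScore]:
    """Per-gene copy-number-altering score k/n over a cohort.

    ``genes`` needs columns gene/chrom/start/end (0-based half-open, as read
    from BED). Genes whose midpoint falls outside the arm map are skipped.
    """
    if direction not in ("gain", "loss"):
        raise ValueError("direction must be 'gain' or 'loss'")
    n = len(profiles)
    out: list[GeneScore] = []
    for row in genes.itertuples(index=False):
        midpoint = (int(row.start) + int(row.end)) // 2
        if arms.assign(str(row.chrom), midpoint) == "unmapped":
            warnings.warn(f"gene {row.gene}: midpoint unmapped, skipped")
            continue
        k = sum(
            _supports(p, arms, str(row.chrom), midpoint, direction, timing_filter)
            for p in profiles
        )
        out.append(GeneScore(str(row.gene), str(row.chrom), midpoint, direction, int(k), n))
    return out


def event_set_profiles(
    profiles: list[TumorProfile], genes: pd.DataFrame, arms: GenomeArms
) -> pd.DataFrame:
    """Genome-ordered before-GD vs after-GD score tracks over the GD samples.

    One row per (gene, direction) with the scores computed separately on the
    pre-GD and post-GD focal event sets (Fig-2B-style tracks).
    """
    gd_profiles = [p for p in profiles if p.gd_status == "GD"]
    rows = []
    for direction in ("gain", "loss"):
        if gd_profiles:
            before = cn_altering_score(gd_profiles, genes, arms, direction, BEFORE_GD)
            after = cn_altering_score(gd_profiles, genes, arms, direction, AFTER_GD)
        else:
            before, after = [], []
        for b, a in zip(before, after):
            rows.append(
                {
                    "gene": b.gene,
                    "chrom": b.chrom,
                    "midpoint": b.midpoint,
                    "direction": direction,
                    "score_before_gd": b.score,
                    "score_after_gd": a.score,
                    "n_gd_samples": b.n,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene", "chrom", "midpoint", "direction",
            "score_before_gd", "score_after_gd", "n_gd_samples",
        ],
    )
    if len(df):
        df["_key"] = df.chrom.str.removeprefix("chr").astype(int)
        df = df.sort_values(["direction", "_key", "midpoint"]).drop(columns="_key")
        df = df.reset_index(drop=True)
    return df


def read_genes_bed(path) -> pd.DataFrame:
    """BED gene table (chrom, start, end, name); 0-based half-open on disk."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "gene"], usecols=[0, 1, 2, 3],
        dtype={0: str},
    )
    return df[["gene", "chrom", "start", "end"]]
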