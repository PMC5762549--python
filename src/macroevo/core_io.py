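"""Domain types, genome coordinate model, and tabular I/O.

In-memory coordinates are 0-based half-open throughout the package; the
on-disk SEG-dialect TSVs are 1-based inclusive (the convention of most
copy-number callers). Conversion happens only at this I/O boundary.

Sex chromosomes may be read but every genome-wide statistic downstream
(GD detection, wGII, LOH fractions) restricts itself to autosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))


class ParseError(ValueError):
    """A malformed row or missing column in an input table."""


class ValidationError(ValueError):
    """A structurally valid row that violates a domain invariant."""


# ---------------------------------------------------------------------------
# genome arm model


@dataclass(frozen=True)
class Arm:
    """One chromosome arm, 0-based half-open.

    The p arm ends at the centromere; the q arm starts at it.
    """

    chrom: str
    arm: str  # "p" or "q"
    start: int
    end: int
    centromere: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(f"bad arm interval {self.chrom}{self.arm}")
        if self.arm not in ("p", "q"):
            raise ValidationError(f"arm label must be p or q, got {self.arm!r}")

    @property
    def name(self) -> str:
        return f"{self.chrom}{self.arm}"

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def telomere_is_start(self) -> bool:
        """p arms run telomere -> centromere left to right."""
        return self.arm == "p"


@dataclass(frozen=True)
class GenomeArms:
    """Arm coordinate frame for one genome assembly (or the toy genome)."""

    arms: tuple[Arm, ...]

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[Arm]] = {}
        for a in self.arms:
            by_chrom.setdefault(a.chrom, []).append(a)
        for chrom, arms in by_chrom.items():
            arms = sorted(arms, key=lambda a: a.start)
            for prev, nxt in zip(arms, arms[1:]):
                if prev.end > nxt.start:
                    raise ValidationError(f"overlapping arms on {chrom}")

    @property
    def chromosomes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for a in self.arms:
            seen.setdefault(a.chrom, None)
        return tuple(seen)

    @property
    def autosomes(self) -> tuple[str, ...]:
        return tuple(c for c in self.chromosomes if c in AUTOSOMES)

    def arms_of(self, chrom: str) -> tuple[Arm, ...]:
        return tuple(a for a in self.arms if a.chrom == chrom)

    def get(self, name: str) -> Arm:
        for a in self.arms:
            if a.name == name:
                return a
        raise KeyError(name)

    def assign(self, chrom: str, pos: int) -> str:
        """Arm name containing a position, or ``"unmapped"``."""
        for a in self.arms:
            if a.chrom == chrom and a.start <= pos < a.end:
                return a.name
        return "unmapped"

    def autosome_length(self) -> int:
        return sum(a.length for a in self.arms if a.chrom in AUTOSOMES)


def toy_genome(
    n_chroms: int = 22, chrom_length: int = 100_000_000, centromere: int = 40_000_000
) -> GenomeArms:
    """Small synthetic arm map: 22 acrocentric-free 100 Mb chromosomes,
    centromere at 40 Mb. Used by the simulator and the test suite."""
    arms = []
    for i in range(1, n_chroms + 1):
        chrom = f"chr{i}"
        arms.append(Arm(chrom, "p", 0, centromere, centromere))
        arms.append(Arm(chrom, "q", centromere, chrom_length, centromere))
    return GenomeArms(tuple(arms))


# ---------------------------------------------------------------------------
# segments and SNVs


@dataclass(frozen=True)
class ASCNSegment:
    """Allele-specific integer copy-number interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    major: int
    minor: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"segment {self.chrom}:{self.start}-{self.end} has start >= end"
            )
        if self.minor < 0 or self.major < self.minor:
            raise ValidationError(
                f"segment {self.chrom}:{self.start}-{self.end}: "
                f"require major >= minor >= 0, got ({self.major},{self.minor})"
            )

    @property
    def total(self) -> int:
        return self.major + self.minor

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def genotype(self) -> tuple[int, int]:
        return (self.major, self.minor)

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class SomaticSNV:
    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float | None = None
    multiplicity: int | None = None
    ccf: float | None = None
    clonal: bool | None = None
    context: str | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValidationError(f"SNV {self.chrom}:{self.pos} has ref == alt")
        if self.vaf is not None and not (0.0 <= self.vaf <= 1.0):
            raise ValidationError(f"SNV {self.chrom}:{self.pos} vaf {self.vaf} not in [0,1]")
        if self.multiplicity is not None and self.multiplicity < 1:
            raise ValidationError(f"SNV {self.chrom}:{self.pos} multiplicity < 1")
        if self.ccf is not None and not (0.0 <= self.ccf <= 1.0):
            raise ValidationError(f"SNV {self.chrom}:{self.pos} ccf not in [0,1]")


@dataclass
class TumorProfile:
    """One sample: purity/ploidy, GD status, segments and SNVs."""

    sample_id: str
    purity: float = 1.0
    ploidy: float = 2.0
    gd_status: str | None = None  # "GD" | "NGD" | None
    segments: list[ASCNSegment] = field(default_factory=list)
    snvs: list[SomaticSNV] = field(default_factory=list)

    def autosomal_segments(self) -> list[ASCNSegment]:
        return [s for s in self.segments if s.chrom in AUTOSOMES]

    def segment_at(self, chrom: str, pos: int) -> ASCNSegment | None:
        for s in self.segments:
            if s.chrom == chrom and s.contains(pos):
                return s
        return None


# ---------------------------------------------------------------------------
# helpers


def _check_no_overlap(segments: Sequence[ASCNSegment]) -> None:
    by_chrom: dict[str, list[ASCNSegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        for prev, nxt in zip(segs, segs[1:]):
            if prev.end > nxt.start:
                raise ValidationError(
                    f"overlapping segments on {chrom}: "
                    f"{prev.start}-{prev.end} and {nxt.start}-{nxt.end}"
                )


def split_at_centromeres(
    segments: Iterable[ASCNSegment], arms: GenomeArms
) -> list[ASCNSegment]:
    """Split any segment straddling a centromere so every segment maps to
    exactly one arm. Segments are never dropped by the split."""
    out: list[ASCNSegment] = []
    for seg in segments:
        pieces = [seg]
        for arm in arms.arms_of(seg.chrom):
            cen = arm.centromere
            next_pieces = []
            for p in pieces:
                if p.start < cen < p.end:
                    next_pieces.append(replace(p, end=cen))
                    next_pieces.append(replace(p, start=cen))
                else:
                    next_pieces.append(p)
            pieces = next_pieces
        out.extend(pieces)
    return sorted(out, key=lambda s: (s.chrom, s.start))


def assign_arm(obj: ASCNSegment | SomaticSNV, arms: GenomeArms) -> str:
    """Unique arm of a (pre-split) segment or an SNV; ``"unmapped"`` off-map."""
    if isinstance(obj, SomaticSNV):
        return arms.assign(obj.chrom, obj.pos)
    name = arms.assign(obj.chrom, obj.start)
    if name == "unmapped":
        return name
    arm = arms.get(name)
    if obj.end > arm.end:
        raise ValidationError(
            f"segment {obj.chrom}:{obj.start}-{obj.end} straddles an arm "
            "boundary; split_at_centromeres() first"
        )
    return name


# ---------------------------------------------------------------------------
# readers / writers (SEG-dialect TSV, 1-based inclusive on disk)

_SEG_COLS = ["chrom", "start", "end", "major", "minor"]
_SNV_COLS = ["chrom", "pos", "ref", "alt"]
_SNV_OPT = ["vaf", "multiplicity", "ccf", "clonal", "context"]


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    return df


def read_segments(path: str | Path, arms: GenomeArms | None = None) -> list[ASCNSegment]:
    """Read a SEG-dialect segment table (1-based inclusive coordinates).

    With an arm map, segments are centromere-split and segments lying
    outside the map are rejected.
    """
    df = _read_tsv(path, _SEG_COLS)
    segments: list[ASCNSegment] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            seg = ASCNSegment(
                chrom=str(row.chrom),
                start=int(row.start) - 1,  # 1-based inclusive -> 0-based half-open
                end=int(row.end),
                major=int(row.major),
                minor=int(row.minor),
            )
        except (TypeError, ValueError) as exc:
            if isinstance(exc, ValidationError):
                raise
            raise ParseError(f"{path} line {i}: {exc}") from exc
        segments.append(seg)
    _check_no_overlap(segments)
    if arms is not None:
        segments = split_at_centromeres(segments, arms)
        for seg in segments:
            if assign_arm(seg, arms) == "unmapped":
                raise ValidationError(
                    f"segment {seg.chrom}:{seg.start}-{seg.end} outside the arm map"
                )
    return segments


def write_segments(segments: Iterable[ASCNSegment], path: str | Path) -> None:
    rows = sorted(segments, key=lambda s: (_chrom_key(s.chrom), s.start))
    df = pd.DataFrame(
        [(s.chrom, s.start + 1, s.end, s.major, s.minor) for s in rows],
        columns=_SEG_COLS,
    )
    df.to_csv(path, sep="\t", index=False)


def _chrom_key(chrom: str) -> tuple[int, str]:
    body = chrom.removeprefix("chr")
    return (int(body), "") if body.isdigit() else (10**6, body)


def read_snvs(path: str | Path) -> list[SomaticSNV]:
    df = _read_tsv(path, _SNV_COLS)
    out: list[SomaticSNV] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()

        def opt(col, cast):
            v = d.get(col)
            if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
                return None
            return cast(v)

        try:
            out.append(
                SomaticSNV(
                    chrom=str(d["chrom"]),
                    pos=int(d["pos"]) - 1,
                    ref=str(d["ref"]),
                    alt=str(d["alt"]),
                    vaf=opt("vaf", float),
                    multiplicity=opt("multiplicity", lambda v: int(float(v))),
                    ccf=opt("ccf", float),
                    clonal=opt("clonal", lambda v: str(v).lower() in ("true", "1")),
                    context=opt("context", str),
                )
            )
        except (TypeError, ValueError) as exc:
            if isinstance(exc, ValidationError):
                raise
            raise ParseError(f"{path} line {i}: {exc}") from exc
    return out


def write_snvs(snvs: Iterable[SomaticSNV], path: str | Path) -> None:
    rows = sorted(snvs, key=lambda v: (_chrom_key(v.chrom), v.pos))
    df = pd.DataFrame(
        [
            (
                v.chrom,
                v.pos + 1,
                v.ref,
                v.alt,
                v.vaf,
                v.multiplicity,
                v.ccf,
                v.clonal,
                v.context,
            )
            for v in rows
        ],
        columns=_SNV_COLS + _SNV_OPT,
    )
    df.to_csv(path, sep="\t", index=False)


def read_samples(path: str | Path) -> pd.DataFrame:
    """samples.tsv: id, purity, ploidy (one row per sample)."""
    df = _read_tsv(path, ["id", "purity", "ploidy"])
    bad = df[(df.purity <= 0) | (df.purity > 1)]
    if len(bad):
        raise ValidationError(f"{path}: purity outside (0,1] for {list(bad.id)}")
    return df


def write_samples(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_arms(path: str | Path) -> GenomeArms:
    """arms.tsv: chrom, arm, start, end, centromere (1-based inclusive)."""
    df = _read_tsv(path, ["chrom", "arm", "start", "end", "centromere"])
    arms = tuple(
        Arm(
            chrom=str(r.chrom),
            arm=str(r.arm),
            start=int(r.start) - 1,
            end=int(r.end),
            centromere=int(r.centromere),
        )
        for r in df.itertuples(index=False)
    )
    return GenomeArms(arms)


def write_arms(arms: GenomeArms, path: str | Path) -> None:
    df = pd.DataFrame(
        [(a.chrom, a.arm, a.start + 1, a.end, a.centromere) for a in arms.arms],
        columns=["chrom", "arm", "start", "end", "centromere"],
    )
    df.to_csv(path, sep="\t", index=False)
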