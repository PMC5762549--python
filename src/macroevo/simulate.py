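"""Synthetic tumor genomes with planted macro-evolutionary histories.

The generator plants an ordered event history (arm losses, gains, uniparental
disomy, telomere-bounded steps, and optionally a whole-genome doubling) on a
diploid genome and realizes it as (a) integer allele-specific copy-number
segments and (b) clonal somatic SNVs laid down by a Poisson process along each
allelic lineage branch. A mutation's multiplicity is the number of final
copies descended from the branch it arose on, so planted molecular times are
recoverable by the multiplicity-based clock and every copy-number estimator
can be checked against the planted truth.

Molecular time is the fraction of total clonal point-mutation accumulation
(0 = tumor initiation, 1 = sampling); the mutation rate is constant in
molecular time by construction. The rate unit is expected clonal SNVs per Mb
per unit molecular time per genome copy: a diploid genome of length L Mb
therefore accumulates ~2·rate·L clonal SNVs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    AUTOSOMES,
    Arm,
    ASCNSegment,
    GenomeArms,
    SomaticSNV,
    TumorProfile,
    toy_genome,
    write_arms,
)

LOSS = "LOSS"
GAIN = "GAIN"
UPD = "UPD"
GD = "GD"
TELOMERE_STEP = "TELOMERE_STEP"

SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class EvolutionEvent:
    kind: str
    t: float
    arm: str | None = None  # arm name, e.g. "chr3q"; None for GD
    allele: str | None = None  # "A" / "B" where applicable
    breakpoint: int | None = None  # TELOMERE_STEP only
    sign: int | None = None  # TELOMERE_STEP only: +1 / -1


@dataclass
class PlantedHistory:
    sample_id: str
    events: list[EvolutionEvent]
    mutation_rate: float = 2.0  # clonal SNVs / Mb / unit time / copy
    subclonal_fraction: float = 0.07
    purity: float = 1.0
    spectrum: tuple[float, ...] = (0.12, 0.10, 0.42, 0.08, 0.20, 0.08)
    apobec_fraction: float = 0.3
    seed: int = 0

    @property
    def gd_time(self) -> float | None:
        for e in self.events:
            if e.kind == GD:
                return e.t
        return None


@dataclass
class SimConfig:
    """Study conditions for a synthetic cohort.

    Defaults emulate the profiled ESCC whole-genome cohort: most samples
    genome-doubled with GD late in molecular time, a handful of arm-level
    losses/gains and copy-neutral events per genome, 5-20 telomere-bounded
    steps, a C>T-dominated substitution spectrum with APOBEC-context
    enrichment, and ~7% subclonal mutations.
    """

    genome: GenomeArms = field(default_factory=toy_genome)
    n_samples: int = 20
    n_losses: int = 6
    n_gains: int = 4
    n_upds: int = 2
    n_telomere_steps: int = 10
    gd_probability: float = 0.8
    gd_time_range: tuple[float, float] = (0.4, 0.9)
    mutation_rate: float = 2.0
    subclonal_fraction: float = 0.07
    purity: float = 1.0
    spectrum: tuple[float, ...] = (0.12, 0.10, 0.42, 0.08, 0.20, 0.08)
    apobec_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_losses", "n_gains", "n_upds", "n_telomere_steps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.gd_probability <= 1.0):
            raise ValueError("gd_probability must be in [0,1]")
        if abs(sum(self.spectrum) - 1.0) > 1e-9:
            raise ValueError("spectrum must sum to 1")


def _sample_seed(seed: int, index: int) -> list[int]:
    return [int(seed) % (2**31), int(index)]


# ---------------------------------------------------------------------------
# history generation


def simulate_history(config: SimConfig, index: int) -> PlantedHistory:
    """Draw one ordered, physically applicable event history.

    Inapplicable draws (e.g. a loss on an arm already down to one copy) are
    re-targeted up to 100 times at the same time point before failing.
    """
    rng = np.random.default_rng(_sample_seed(config.seed, index) + [0])
    auto_arms = [a for a in config.genome.arms if a.chrom in AUTOSOMES]

    drawn: list[tuple[float, str]] = []
    if rng.random() < config.gd_probability:
        lo, hi = config.gd_time_range
        drawn.append((float(rng.uniform(lo, hi)), GD))
    for kind, n in (
        (LOSS, config.n_losses),
        (GAIN, config.n_gains),
        (UPD, config.n_upds),
        (TELOMERE_STEP, config.n_telomere_steps),
    ):
        for _ in range(n):
            drawn.append((float(rng.uniform(0, 1)), kind))
    drawn.sort(key=lambda x: x[0])

    # arm-level allele counts and telomeric step ledger, for applicability;
    # tel_steps holds (distance from centromere, signed magnitude) per arm
    counts: dict[str, list[int]] = {a.name: [1, 1] for a in auto_arms}
    tel_steps: dict[str, list[list[int]]] = {a.name: [] for a in auto_arms}

    def _tel_min_beyond(arm_name: str, d_new: int, sign: int) -> int:
        """Minimum piecewise total CN over regions telomeric of the new
        breakpoint, with the candidate step applied (conservative: treats
        every arm-level event as acting on the whole arm)."""
        steps = tel_steps[arm_name] + [[d_new, sign]]
        total = counts[arm_name][0] + counts[arm_name][1]
        best = None
        for d, mag in sorted(steps):
            total += mag
            if d >= d_new:
                best = total if best is None else min(best, total)
        return best

    events: list[EvolutionEvent] = []
    for t, kind in drawn:
        if kind == GD:
            for c in counts.values():
                c[0] *= 2
                c[1] *= 2
            for steps in tel_steps.values():
                for s in steps:
                    s[1] *= 2
            events.append(EvolutionEvent(GD, t))
            continue
        placed = False
        for _ in range(100):
            arm = auto_arms[rng.integers(len(auto_arms))]
            ai = int(rng.integers(2))
            c = counts[arm.name]
            if kind == LOSS:
                if c[ai] >= 1 and c[0] + c[1] >= 2:
                    c[ai] -= 1
                    events.append(EvolutionEvent(LOSS, t, arm.name, "AB"[ai]))
                    placed = True
            elif kind == GAIN:
                if c[ai] >= 1:
                    c[ai] += 1
                    events.append(EvolutionEvent(GAIN, t, arm.name, "AB"[ai]))
                    placed = True
            elif kind == UPD:
                if c[ai] >= 1 and c[1 - ai] >= 1:
                    c[ai] -= 1
                    c[1 - ai] += 1
                    events.append(EvolutionEvent(UPD, t, arm.name, "AB"[ai]))
                    placed = True
            elif kind == TELOMERE_STEP:
                sign = int(rng.choice([1, -1]))
                span = arm.length
                bp = int(arm.start + rng.integers(int(0.1 * span), int(0.9 * span)))
                d = (arm.end - bp) if arm.telomere_is_start else (bp - arm.start)
                existing = {
                    e.breakpoint for e in events if e.kind == TELOMERE_STEP and e.arm == arm.name
                }
                if bp not in existing and (
                    sign > 0 or _tel_min_beyond(arm.name, d, sign) >= 1
                ):
                    tel_steps[arm.name].append([d, sign])
                    events.append(
                        EvolutionEvent(TELOMERE_STEP, t, arm.name, "AB"[ai], bp, sign)
                    )
                    placed = True
            if placed:
                break
        if not placed:
            raise RuntimeError(f"could not place {kind} event at t={t:.3f}")

    return PlantedHistory(
        sample_id=f"SIM-{index:03d}",
        events=events,
        mutation_rate=config.mutation_rate,
        subclonal_fraction=config.subclonal_fraction,
        purity=config.purity,
        spectrum=config.spectrum,
        apobec_fraction=config.apobec_fraction,
        seed=int(np.random.default_rng(_sample_seed(config.seed, index)).integers(2**31)),
    )


# ---------------------------------------------------------------------------
# lineage realization


class _Node:
    __slots__ = ("allele", "t0", "t1", "children", "dead", "ndesc")

    def __init__(self, allele: str, t0: float):
        self.allele = allele
        self.t0 = t0
        self.t1: float | None = None
        self.children: list[_Node] = []
        self.dead = False
        self.ndesc = 0


def _duplicate(node: _Node, t: float, live: list[_Node]) -> None:
    node.t1 = t
    node.children = [_Node(node.allele, t), _Node(node.allele, t)]
    live.remove(node)
    live.extend(node.children)


def _kill(node: _Node, t: float, live: list[_Node]) -> None:
    node.t1 = t
    node.dead = True
    live.remove(node)


def _count_desc(node: _Node) -> int:
    if node.children:
        node.ndesc = sum(_count_desc(c) for c in node.children)
    else:
        node.ndesc = 0 if node.dead else 1
    return node.ndesc


def _all_nodes(roots: list[_Node]) -> list[_Node]:
    out, stack = [], list(roots)
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(n.children)
    return out


def _simulate_region(
    events: list[EvolutionEvent], rng: np.random.Generator
) -> tuple[list[_Node], list[_Node], tuple[int, int] | None]:
    """Run the lineage forest of one genomic region through its events.

    Returns (roots, live leaves, genotype (nA, nB) immediately before GD or
    None when no GD applies to the region). Events that find no applicable
    copy in this region (e.g. the allele is already absent here) are no-ops.
    """
    roots = [_Node("A", 0.0), _Node("B", 0.0)]
    live = list(roots)
    pre_gd: tuple[int, int] | None = None

    def pick(allele: str | None) -> _Node | None:
        cands = live if allele is None else [n for n in live if n.allele == allele]
        if not cands:
            return None
        return cands[int(rng.integers(len(cands)))]

    for e in sorted(events, key=lambda e: e.t):
        if e.kind == GD:
            pre_gd = (
                sum(1 for n in live if n.allele == "A"),
                sum(1 for n in live if n.allele == "B"),
            )
            for n in list(live):
                _duplicate(n, e.t, live)
        elif e.kind == LOSS:
            n = pick(e.allele)
            if n is not None and len(live) >= 2:
                _kill(n, e.t, live)
        elif e.kind == GAIN:
            n = pick(e.allele)
            if n is not None:
                _duplicate(n, e.t, live)
        elif e.kind == UPD:
            lost = pick(e.allele)
            other = pick("B" if e.allele == "A" else "A")
            if lost is not None and other is not None:
                _kill(lost, e.t, live)
                _duplicate(other, e.t, live)
        elif e.kind == TELOMERE_STEP:
            if e.sign == 1:
                n = pick(e.allele) or pick(None)
                if n is not None:
                    _duplicate(n, e.t, live)
            else:
                n = pick(e.allele) or pick(None)
                if n is not None:
                    _kill(n, e.t, live)
    for n in live:
        n.t1 = 1.0
    for r in roots:
        _count_desc(r)
    return roots, live, pre_gd


def _region_events(arm: Arm, start: int, end: int, events: list[EvolutionEvent]) -> list[EvolutionEvent]:
    out = []
    for e in events:
        if e.kind == GD:
            out.append(e)
        elif e.arm != arm.name:
            continue
        elif e.kind == TELOMERE_STEP:
            if arm.telomere_is_start:
                if end <= e.breakpoint:  # interval [arm.start, bp)
                    out.append(e)
            else:
                if start >= e.breakpoint:  # interval [bp, arm.end)
                    out.append(e)
        else:
            out.append(e)
    return out


def _draw_substitution(
    rng: np.random.Generator, spectrum: np.ndarray, apobec_fraction: float
) -> tuple[str, str, str]:
    """Sample (ref, alt, trinucleotide context), randomly strand-flipped."""
    cls = SPECTRUM_CLASSES[int(rng.choice(6, p=spectrum))]
    ref, alt = cls[0], cls[2]
    bases = "ACGT"
    if ref == "C" and alt in "GT" and rng.random() < apobec_fraction:
        left, right = "T", "AT"[int(rng.integers(2))]
    else:
        left, right = bases[int(rng.integers(4))], bases[int(rng.integers(4))]
    context = left + ref + right
    if rng.random() < 0.5:  # report on the opposite strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        context = "".join(_COMPLEMENT[b] for b in reversed(context))
    return ref, alt, context


def _vaf(mult: int, total: int, purity: float) -> float:
    if total == 0:
        return 0.0
    return mult * purity / (purity * total + 2.0 * (1.0 - purity))


def realize_profile(
    history: PlantedHistory, genome: GenomeArms | None = None
) -> tuple[TumorProfile, dict]:
    """Realize a planted history as a TumorProfile plus truth tables.

    Truth dict keys:
      ``regions``   — DataFrame: chrom/start/end/arm/major/minor, genotype at
                      GD, and the NLOH mechanism label where minor == 0;
      ``events``    — DataFrame of the planted events with pre/post-GD flags;
      ``gd_time``   — planted GD molecular time or None.
    """
    genome = genome or toy_genome()
    rng = np.random.default_rng(_sample_seed(history.seed, 1))
    auto_arms = [a for a in genome.arms if a.chrom in AUTOSOMES]
    gd_time = history.gd_time
    spectrum = np.asarray(history.spectrum, dtype=float)
    apobec = history.apobec_fraction

    segments: list[ASCNSegment] = []
    snvs: list[SomaticSNV] = []
    truth_rows = []

    for arm in auto_arms:
        bps = sorted(
            {e.breakpoint for e in history.events if e.kind == TELOMERE_STEP and e.arm == arm.name}
        )
        bounds = [arm.start] + bps + [arm.end]
        arm_segments: list[ASCNSegment] = []
        for start, end in zip(bounds, bounds[1:]):
            evs = _region_events(arm, start, end, history.events)
            roots, live, pre_gd = _simulate_region(evs, rng)
            n_a = sum(1 for n in live if n.allele == "A")
            n_b = sum(1 for n in live if n.allele == "B")
            major, minor = max(n_a, n_b), min(n_a, n_b)
            length_mb = (end - start) / 1e6
            total = major + minor

            mechanism = None
            if minor == 0 and major >= 2:
                if (
                    gd_time is not None
                    and pre_gd is not None
                    and sorted(pre_gd) == [0, 1]
                    and major == 2
                ):
                    mechanism = "GD_derived"
                else:
                    mechanism = "intrinsic"

            if total > 0:
                arm_segments.append(ASCNSegment(arm.chrom, start, end, major, minor))
            truth_rows.append(
                {
                    "sample": history.sample_id,
                    "chrom": arm.chrom,
                    "start": start,
                    "end": end,
                    "arm": arm.name,
                    "major": major,
                    "minor": minor,
                    "genotype_at_gd": None if pre_gd is None else f"{pre_gd[0]},{pre_gd[1]}",
                    "nloh_mechanism": mechanism,
                }
            )

            # clonal mutations along each surviving lineage branch
            for node in _all_nodes(roots):
                if node.ndesc == 0:
                    continue
                lam = history.mutation_rate * length_mb * (node.t1 - node.t0)
                k = int(rng.poisson(lam))
                if k == 0:
                    continue
                positions = rng.integers(start, end, size=k)
                for pos in positions:
                    ref, alt, ctx = _draw_substitution(rng, spectrum, apobec)
                    snvs.append(
                        SomaticSNV(
                            chrom=arm.chrom,
                            pos=int(pos),
                            ref=ref,
                            alt=alt,
                            vaf=_vaf(node.ndesc, total, history.purity),
                            multiplicity=int(node.ndesc),
                            ccf=1.0,
                            clonal=True,
                            context=ctx,
                        )
                    )
        # merge contiguous equal-genotype regions within the arm
        merged: list[ASCNSegment] = []
        for seg in arm_segments:
            if merged and merged[-1].end == seg.start and merged[-1].genotype == seg.genotype:
                merged[-1] = ASCNSegment(
                    seg.chrom, merged[-1].start, seg.end, seg.major, seg.minor
                )
            else:
                merged.append(seg)
        segments.extend(merged)

    # subclonal pool: CCF-labelled, multiplicity 1, excluded from timing
    n_sub = int(rng.poisson(history.subclonal_fraction * len(snvs)))
    if n_sub and segments:
        lengths = np.array([s.length for s in segments], dtype=float)
        seg_idx = rng.choice(len(segments), size=n_sub, p=lengths / lengths.sum())
        for i in seg_idx:
            seg = segments[int(i)]
            pos = int(rng.integers(seg.start, seg.end))
            ccf = float(rng.uniform(0.1, 0.6))
            ref, alt, ctx = _draw_substitution(rng, spectrum, apobec)
            snvs.append(
                SomaticSNV(
                    chrom=seg.chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    vaf=ccf * _vaf(1, seg.total, history.purity),
                    multiplicity=1,
                    ccf=ccf,
                    clonal=False,
                    context=ctx,
                )
            )

    profile = TumorProfile(
        sample_id=history.sample_id,
        purity=history.purity,
        ploidy=_ploidy(segments),
        gd_status="GD" if gd_time is not None else "NGD",
        segments=sorted(segments, key=lambda s: (s.chrom, s.start)),
        snvs=snvs,
    )
    truth = {
        "regions": pd.DataFrame(truth_rows),
        "events": pd.DataFrame(
            [
                {
                    "sample": history.sample_id,
                    "kind": e.kind,
                    "t": e.t,
                    "arm": e.arm,
                    "allele": e.allele,
                    "breakpoint": e.breakpoint,
                    "sign": e.sign,
                    "pre_gd": None if gd_time is None else e.t < gd_time,
                }
                for e in history.events
            ]
        ),
        "gd_time": gd_time,
    }
    return profile, truth


def _ploidy(segments: list[ASCNSegment]) -> float:
    tot = sum(s.length for s in segments)
    if tot == 0:
        return 2.0
    return sum(s.total * s.length for s in segments) / tot


# ---------------------------------------------------------------------------
# cohort emission


def emit_cohort(config: SimConfig, outdir: str | Path) -> Path:
    """Simulate ``config.n_samples`` tumors and write the cohort tables.

    Layout: segments.tsv / snvs.tsv / samples.tsv / arms.tsv (core_io
    formats with a leading ``sample`` column on the per-sample tables) and
    truth/{samples,events,regions}.tsv. Byte-deterministic under the seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)

    seg_frames, snv_frames, sample_rows = [], [], []
    truth_events, truth_regions, truth_samples = [], [], []
    for i in range(config.n_samples):
        history = simulate_history(config, i)
        profile, truth = realize_profile(history, config.genome)
        seg_frames.append(
            pd.DataFrame(
                [
                    (profile.sample_id, s.chrom, s.start + 1, s.end, s.major, s.minor)
                    for s in profile.segments
                ],
                columns=["sample", "chrom", "start", "end", "major", "minor"],
            )
        )
        snv_frames.append(
            pd.DataFrame(
                [
                    (
                        profile.sample_id,
                        v.chrom,
                        v.pos + 1,
                        v.ref,
                        v.alt,
                        round(v.vaf, 6),
                        v.multiplicity,
                        v.ccf,
                        v.clonal,
                        v.context,
                    )
                    for v in sorted(profile.snvs, key=lambda v: (v.chrom, v.pos))
                ],
                columns=[
                    "sample", "chrom", "pos", "ref", "alt",
                    "vaf", "multiplicity", "ccf", "clonal", "context",
                ],
            )
        )
        sample_rows.append((profile.sample_id, profile.purity, round(profile.ploidy, 4)))
        truth_events.append(truth["events"])
        truth_regions.append(truth["regions"])
        truth_samples.append(
            {
                "sample": profile.sample_id,
                "gd": truth["gd_time"] is not None,
                "gd_time": truth["gd_time"],
                "seed": history.seed,
            }
        )

    def cat(frames, cols):
        if frames:
            return pd.concat(frames, ignore_index=True)
        return pd.DataFrame(columns=cols)

    cat(seg_frames, ["sample", "chrom", "start", "end", "major", "minor"]).to_csv(
        outdir / "segments.tsv", sep="\t", index=False
    )
    cat(
        snv_frames,
        ["sample", "chrom", "pos", "ref", "alt", "vaf", "multiplicity", "ccf", "clonal", "context"],
    ).to_csv(outdir / "snvs.tsv", sep="\t", index=False)
    pd.DataFrame(sample_rows, columns=["id", "purity", "ploidy"]).to_csv(
        outdir / "samples.tsv", sep="\t", index=False
    )
    write_arms(config.genome, outdir / "arms.tsv")
    cat(truth_events, ["sample", "kind", "t", "arm", "allele", "breakpoint", "sign", "pre_gd"]).to_csv(
        outdir / "truth" / "events.tsv", sep="\t", index=False
    )
    cat(
        truth_regions,
        ["sample", "chrom", "start", "end", "arm", "major", "minor", "genotype_at_gd", "nloh_mechanism"],
    ).to_csv(outdir / "truth" / "regions.tsv", sep="\t", index=False)
    pd.DataFrame(truth_samples, columns=["sample", "gd", "gd_time", "seed"]).to_csv(
        outdir / "truth" / "samples.tsv", sep="\t", index=False
    )
    return outdir
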