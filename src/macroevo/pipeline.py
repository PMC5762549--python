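"""End-to-end orchestration: simulate -> gd-call -> scna -> loh -> clock ->
tcna -> spectrum -> summary, with a machine-readable manifest.

Every stage reads/writes plain TSVs under the run directory, all randomness
is funneled through per-stage generators derived from one seed, and a rerun
with the same config reproduces the outputs byte for byte (the manifest
carries versions, seeds and thresholds, and no timestamps).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clock import MODE_FRACTION, gain_time_summary, time_first_nloh, time_gd
from .core_io import (
    ASCNSegment,
    GenomeArms,
    SomaticSNV,
    TumorProfile,
    read_arms,
    split_at_centromeres,
    toy_genome,
)
from .loh import (
    ARM_LEVEL_FRACTION,
    arm_loh_proportions,
    detect_loh,
    genome_fraction_by_mechanism,
    nloh_counts,
    partition_nloh,
)
from .ploidy import (
    GD_FRACTION_THRESHOLD,
    GD_N_SIMS,
    GD_P_THRESHOLD,
    detect_gd,
    gd_timing_by_losses,
    wgii,
)
from .scna import FOCAL_CN_CAP, SCORE_THRESHOLD, cn_altering_score, event_set_profiles, read_genes_bed
from .simulate import SimConfig, emit_cohort
from .spectrum import (
    CCF_CLONAL_THRESHOLD,
    apobec_context_fraction,
    classify_clonality,
    estimate_multiplicity,
    gd_spectrum_compare,
    spectrum,
)
from .tcna import tcna_summary

log = logging.getLogger("macroevo")

THRESHOLDS = {
    "gd_fraction": GD_FRACTION_THRESHOLD,
    "gd_p": GD_P_THRESHOLD,
    "gd_n_sims": GD_N_SIMS,
    "mode_fraction": MODE_FRACTION,
    "score": SCORE_THRESHOLD,
    "arm_level_fraction": ARM_LEVEL_FRACTION,
    "ccf_clonal": CCF_CLONAL_THRESHOLD,
    "focal_cn_cap": FOCAL_CN_CAP,
}

ALL_STAGES = ("gd", "scna", "loh", "clock", "tcna", "spectrum")


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    segments: str | None = None
    snvs: str | None = None
    samples: str | None = None
    arms: str | None = None
    genes: str | None = None
    simulate: dict | None = None  # SimConfig keyword overrides; triggers simulation
    n_sims: int = GD_N_SIMS
    stages: tuple[str, ...] = ALL_STAGES

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# cohort loading


def load_cohort(
    segments_path: str | Path,
    samples_path: str | Path,
    arms: GenomeArms,
    snvs_path: str | Path | None = None,
) -> list[TumorProfile]:
    """Load cohort tables (core_io formats with a leading ``sample`` column)
    into per-sample profiles; fill in multiplicity/clonality where the SNV
    table leaves them unset."""
    seg_df = pd.read_csv(segments_path, sep="\t", comment="#", dtype={"chrom": str})
    sample_df = pd.read_csv(samples_path, sep="\t", comment="#")
    snv_df = None
    if snvs_path is not None:
        snv_df = pd.read_csv(snvs_path, sep="\t", comment="#", dtype={"chrom": str})

    profiles = []
    for row in sample_df.itertuples(index=False):
        sid = str(row.id)
        segs = [
            ASCNSegment(str(r.chrom), int(r.start) - 1, int(r.end), int(r.major), int(r.minor))
            for r in seg_df[seg_df["sample"].astype(str) == sid].itertuples(index=False)
        ]
        segs = split_at_centromeres(segs, arms)
        profile = TumorProfile(
            sample_id=sid,
            purity=float(row.purity),
            ploidy=float(row.ploidy),
            segments=segs,
        )
        if snv_df is not None:
            snvs = []
            for r in snv_df[snv_df["sample"].astype(str) == sid].itertuples(index=False):
                d = r._asdict()

                def opt(col, cast):
                    v = d.get(col)
                    if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
                        return None
                    return cast(v)

                snv = SomaticSNV(
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
                snvs.append(_complete_snv(snv, profile))
            profile.snvs = snvs
        profiles.append(profile)
    return profiles


def _complete_snv(snv: SomaticSNV, profile: TumorProfile) -> SomaticSNV:
    from dataclasses import replace

    if snv.multiplicity is None and snv.vaf is not None:
        seg = profile.segment_at(snv.chrom, snv.pos)
        if seg is not None and seg.total >= 1:
            snv = replace(
                snv,
                multiplicity=estimate_multiplicity(snv, profile.purity, seg.genotype),
            )
    if snv.clonal is None and snv.ccf is not None:
        snv = replace(snv, clonal=classify_clonality(snv) == "clonal")
    return snv


def tile_genes(arms: GenomeArms, step: int = 20_000_000) -> pd.DataFrame:
    """Fallback gene grid (one locus per ``step`` bp) when no gene table is
    supplied, so the score tracks still cover the genome."""
    rows = []
    i = 0
    for arm in arms.arms:
        pos = arm.start
        while pos + step <= arm.end:
            rows.append({"gene": f"locus_{i:03d}", "chrom": arm.chrom, "start": pos, "end": pos + step})
            pos += step
            i += 1
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


# ---------------------------------------------------------------------------
# stages


def stage_gd(profiles, arms, outdir: Path, n_sims: int, seed: int) -> pd.DataFrame:
    rows = []
    for i, p in enumerate(profiles):
        call = detect_gd(p, arms, n_sims=n_sims, seed=np.random.default_rng([seed % 2**31, 11, i]))
        p.gd_status = "GD" if call.gd else "NGD"
        timing = gd_timing_by_losses(p) if call.gd else None
        rows.append(
            {
                "sample": p.sample_id,
                "gd": call.gd,
                "major2_fraction": round(call.major2_fraction, 6),
                "p_value": call.p_value,
                "n_arm_events": call.n_arm_events,
                "wgii": round(wgii(p), 6),
                "gd_timing_class": timing.timing_class if timing else "",
                "proportion_ab": round(timing.proportion_ab, 6) if timing else "",
                "proportion_aa_bb": round(timing.proportion_aa_bb, 6) if timing else "",
            }
        )
        log.info("stage=gd sample=%s gd=%s", p.sample_id, call.gd)
    df = pd.DataFrame(
        rows,
        columns=[
            "sample", "gd", "major2_fraction", "p_value", "n_arm_events",
            "wgii", "gd_timing_class", "proportion_ab", "proportion_aa_bb",
        ],
    )
    df.to_csv(outdir / "gd.tsv", sep="\t", index=False)
    return df


def stage_scna(profiles, arms, genes: pd.DataFrame, outdir: Path) -> pd.DataFrame:
    tracks = event_set_profiles(profiles, genes, arms)
    overall = []
    for direction in ("gain", "loss"):
        for s in cn_altering_score(profiles, genes, arms, direction):
            overall.append(
                {
                    "gene": s.gene,
                    "chrom": s.chrom,
                    "midpoint": s.midpoint,
                    "direction": direction,
                    "score": round(s.score, 6),
                    "frequent": s.frequent,
                }
            )
    pd.DataFrame(
        overall, columns=["gene", "chrom", "midpoint", "direction", "score", "frequent"]
    ).to_csv(outdir / "scores.tsv", sep="\t", index=False)
    tracks.to_csv(outdir / "event_set_tracks.tsv", sep="\t", index=False)
    log.info("stage=scna genes=%d", len(genes))
    return tracks


def stage_loh(profiles, arms, outdir: Path) -> pd.DataFrame:
    all_events, event_rows, sample_rows = [], [], []
    for p in profiles:
        events = partition_nloh(detect_loh(p, arms), p.gd_status == "GD")
        all_events.append(events)
        for e in events:
            event_rows.append(
                {
                    "sample": e.sample_id,
                    "chrom": e.chrom,
                    "start": e.start + 1,
                    "end": e.end,
                    "major": e.major,
                    "category": e.category,
                    "mechanism": e.mechanism or "",
                    "arm": e.arm,
                    "arm_level": e.arm_level,
                }
            )
        gd_frac, intrinsic_frac = genome_fraction_by_mechanism(events, p)
        sample_rows.append(
            {
                "sample": p.sample_id,
                "gd_derived_fraction": round(gd_frac, 6),
                "intrinsic_fraction": round(intrinsic_frac, 6),
                **{k: round(v, 6) if isinstance(v, float) else v for k, v in nloh_counts(events).items()},
            }
        )
        log.info("stage=loh sample=%s events=%d", p.sample_id, len(events))
    pd.DataFrame(
        event_rows,
        columns=["sample", "chrom", "start", "end", "major", "category", "mechanism", "arm", "arm_level"],
    ).to_csv(outdir / "loh_events.tsv", sep="\t", index=False)
    arm_loh_proportions(all_events, arms).to_csv(outdir / "arm_loh.tsv", sep="\t", index=False)
    df = pd.DataFrame(sample_rows)
    df.to_csv(outdir / "loh_samples.tsv", sep="\t", index=False)
    return df


def stage_clock(profiles, arms, outdir: Path) -> pd.DataFrame:
    rows = []
    for p in profiles:
        gd_t = None
        if p.gd_status == "GD":
            res = time_gd(p, arms)
            gd_t = res.t
        first_nloh, _ = time_first_nloh(p, arms)
        summary = gain_time_summary(p, arms)
        rows.append(
            {
                "sample": p.sample_id,
                "gd_time": round(gd_t, 6) if gd_t is not None else "",
                "first_nloh_time": round(first_nloh.t, 6) if first_nloh else "",
                "n_gains_timed": summary["n_timed"],
                "gain_time_min": round(summary["min"], 6) if summary["min"] is not None else "",
                "gain_time_median": round(summary["median"], 6) if summary["median"] is not None else "",
                "gain_time_span": round(summary["span"], 6) if summary["span"] is not None else "",
                "punctuated": summary["punctuated"],
            }
        )
        log.info("stage=clock sample=%s gd_time=%s", p.sample_id, gd_t)
    df = pd.DataFrame(
        rows,
        columns=[
            "sample", "gd_time", "first_nloh_time", "n_gains_timed",
            "gain_time_min", "gain_time_median", "gain_time_span", "punctuated",
        ],
    )
    df.to_csv(outdir / "timing.tsv", sep="\t", index=False)
    return df


def stage_tcna(profiles, arms, outdir: Path) -> pd.DataFrame:
    per_sample, per_arm, events = tcna_summary(profiles, arms)
    events.to_csv(outdir / "tcna_events.tsv", sep="\t", index=False)
    per_arm.to_csv(outdir / "tcna_arms.tsv", sep="\t", index=False)
    per_sample.to_csv(outdir / "tcna_samples.tsv", sep="\t", index=False)
    log.info("stage=tcna events=%d", len(events))
    return per_sample


def stage_spectrum(profiles, arms, outdir: Path) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for stratum, subset in (
            ("all", p.snvs),
            ("clonal", [v for v in p.snvs if v.clonal]),
            ("subclonal", [v for v in p.snvs if v.clonal is False]),
        ):
            vec = spectrum(subset, p.sample_id, stratum)
            try:
                apobec = apobec_context_fraction(subset)
            except ValueError:
                apobec = None
            rows.append(
                {
                    "sample": p.sample_id,
                    "stratum": stratum,
                    "n": vec.n,
                    **{c: round(x, 6) for c, x in zip(("C_A", "C_G", "C_T", "T_A", "T_C", "T_G"), vec.proportions)},
                    "apobec_tcw_fraction": round(apobec, 6) if apobec is not None else "",
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "spectrum.tsv", sep="\t", index=False)
    try:
        compare = gd_spectrum_compare(profiles, arms)
        compare.to_csv(outdir / "spectrum_gd_compare.tsv", sep="\t", index=False)
    except ValueError as exc:
        log.info("stage=spectrum gd-compare skipped: %s", exc)
    log.info("stage=spectrum samples=%d", len(profiles))
    return df


# ---------------------------------------------------------------------------
# driver


def run_pipeline(config: RunConfig) -> Path:
    """Run all configured stages; returns the report directory.

    A stage failure raises ``RuntimeError`` naming the stage; outputs of
    completed stages are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.seed)
        sim = SimConfig(**sim_kwargs)
        cohort_dir = emit_cohort(sim, outdir / "cohort")
        config.segments = str(cohort_dir / "segments.tsv")
        config.snvs = str(cohort_dir / "snvs.tsv")
        config.samples = str(cohort_dir / "samples.tsv")
        config.arms = str(cohort_dir / "arms.tsv")
        log.info("stage=simulate samples=%d", sim.n_samples)

    arms = read_arms(config.arms) if config.arms else toy_genome()
    profiles = load_cohort(config.segments, config.samples, arms, config.snvs)
    genes = read_genes_bed(config.genes) if config.genes else tile_genes(arms)

    results: dict[str, pd.DataFrame] = {}
    stage_fns = {
        "gd": lambda: stage_gd(profiles, arms, outdir, config.n_sims, config.seed),
        "scna": lambda: stage_scna(profiles, arms, genes, outdir),
        "loh": lambda: stage_loh(profiles, arms, outdir),
        "clock": lambda: stage_clock(profiles, arms, outdir),
        "tcna": lambda: stage_tcna(profiles, arms, outdir),
        "spectrum": lambda: stage_spectrum(profiles, arms, outdir),
    }
    for name in config.stages:
        try:
            results[name] = stage_fns[name]()
        except Exception as exc:  # noqa: BLE001 - stage-named rethrow
            raise RuntimeError(f"stage {name} failed: {exc}") from exc

    _write_summary(profiles, results, outdir)
    manifest = {
        "package": "macroevo",
        "version": __version__,
        "seed": config.seed,
        "n_sims": config.n_sims,
        "thresholds": THRESHOLDS,
        "stages": list(config.stages),
        "inputs": {
            "segments": Path(config.segments).name if config.segments else None,
            "snvs": Path(config.snvs).name if config.snvs else None,
            "samples": Path(config.samples).name if config.samples else None,
            "arms": Path(config.arms).name if config.arms else None,
            "genes": Path(config.genes).name if config.genes else None,
        },
        "n_samples": len(profiles),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir


def _write_summary(profiles, results: dict, outdir: Path) -> None:
    cols = [
        "sample", "gd", "wgii", "gd_timing_class", "gd_time", "first_nloh_time",
        "intrinsic_fraction", "n_tcna", "gain_time_span", "punctuated",
    ]
    frames = []
    base = pd.DataFrame({"sample": [p.sample_id for p in profiles]})
    frames.append(base)
    merged = base
    for key, use in (
        ("gd", ["sample", "gd", "wgii", "gd_timing_class"]),
        ("loh", ["sample", "intrinsic_fraction"]),
        ("clock", ["sample", "gd_time", "first_nloh_time", "gain_time_span", "punctuated"]),
        ("tcna", ["sample", "n_tcna"]),
    ):
        if key in results and len(results[key]):
            merged = merged.merge(results[key][use], on="sample", how="left")
    for c in cols:
        if c not in merged.columns:
            merged[c] = ""
    merged[cols].to_csv(outdir / "summary.tsv", sep="\t", index=False)
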