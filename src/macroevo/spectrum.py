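"""Mutation-level metrics: multiplicity estimation, clonality, spectra.

The multiplicity estimator inverts the bulk VAF model
``vaf = m * purity / (purity * CN_total + 2 (1 - purity))`` by rounding, then
clips into [1, major CN]. Clonality is a CCF threshold call (clonal iff
CCF >= 0.9). Spectra are six-class substitution proportions in pyrimidine
orientation; the pre-/post-GD comparison strata are clonal SNVs in doubled
(2:2) regions with multiplicity >= 2 (before GD) vs multiplicity 1 (after).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import AUTOSOMES, ASCNSegment, GenomeArms, SomaticSNV, TumorProfile
from .clock import merge_arm_mode

CCF_CLONAL_THRESHOLD = 0.9
CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class SpectrumVector:
    sample_id: str
    stratum: str
    proportions: tuple[float, ...]  # CLASSES order; all-zero for empty strata
    n: int


def estimate_multiplicity(
    snv: SomaticSNV, purity: float, genotype: tuple[int, int]
) -> int:
    """Nearest-integer multiplicity from VAF, purity and the local genotype."""
    if snv.vaf is None:
        raise ValueError(f"SNV {snv.chrom}:{snv.pos}: vaf unset")
    if not (0.0 < purity <= 1.0):
        raise ValueError("purity must be in (0, 1]")
    major, minor = genotype
    total = major + minor
    if total < 1:
        raise ValueError("segment total CN must be >= 1")
    m = round(snv.vaf * (purity * total + 2.0 * (1.0 - purity)) / purity)
    return int(min(max(m, 1), major))


def classify_clonality(snv: SomaticSNV) -> str:
    """clonal iff CCF >= 0.9 (inclusive)."""
    if snv.ccf is None:
        raise ValueError(f"SNV {snv.chrom}:{snv.pos}: ccf unset")
    return "clonal" if snv.ccf >= CCF_CLONAL_THRESHOLD else "subclonal"


def substitution_class(ref: str, alt: str) -> str | None:
    """Six-class label in pyrimidine orientation; None for non-ACGT alleles."""
    if ref not in "ACGT" or alt not in "ACGT" or ref == alt:
        return None
    if ref in "AG":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


def spectrum(
    snvs: list[SomaticSNV], sample_id: str = "", stratum: str = ""
) -> SpectrumVector:
    counts = dict.fromkeys(CLASSES, 0)
    skipped = 0
    for v in snvs:
        cls = substitution_class(v.ref, v.alt)
        if cls is None:
            skipped += 1
            continue
        counts[cls] += 1
    if skipped:
        warnings.warn(f"{skipped} SNV(s) with non-ACGT alleles skipped")
    n = sum(counts.values())
    props = tuple(counts[c] / n for c in CLASSES) if n else (0.0,) * 6
    return SpectrumVector(sample_id, stratum, props, n)


def gd_strata(profile: TumorProfile, arms: GenomeArms) -> tuple[list[SomaticSNV], list[SomaticSNV]]:
    """(before-GD, after-GD) clonal SNV strata from 2:2-mode regions."""
    regions: list[ASCNSegment] = []
    for arm in arms.arms:
        if arm.chrom not in AUTOSOMES:
            continue
        mode = merge_arm_mode(profile, arms, arm.name)
        if mode is not None and mode[0] == (2, 2):
            regions.extend(mode[1])
    before, after = [], []
    for v in profile.snvs:
        if not v.clonal or v.multiplicity is None:
            continue
        if not any(s.chrom == v.chrom and s.contains(v.pos) for s in regions):
            continue
        (before if v.multiplicity >= 2 else after).append(v)
    return before, after


def spectrum_ranksum_table(
    before: np.ndarray, after: np.ndarray
) -> pd.DataFrame:
    """Per-class two-sided rank-sum comparison of spectrum proportions.

    ``before``/``after`` are (n_samples, 6) proportion matrices. Uses the
    tie-corrected normal approximation.
    """
    if before.shape[0] < 2 or after.shape[0] < 2:
        raise ValueError("need at least 2 samples per stratum")
    rows = []
    for j, cls in enumerate(CLASSES):
        x, y = before[:, j], after[:, j]
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            stat, p = 0.0, 1.0  # identical constant groups: no evidence
        else:
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "class": cls,
                "mean_before": float(x.mean()),
                "mean_after": float(y.mean()),
                "statistic": stat,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def gd_spectrum_compare(
    profiles: list[TumorProfile], arms: GenomeArms
) -> pd.DataFrame:
    """Mutational-spectrum comparison before vs after GD across GD samples."""
    gd_profiles = [p for p in profiles if p.gd_status == "GD"]
    if len(gd_profiles) < 2:
        raise ValueError("need at least 2 GD samples")
    before_rows, after_rows = [], []
    for p in gd_profiles:
        b, a = gd_strata(p, arms)
        before_rows.append(spectrum(b, p.sample_id, "before_GD").proportions)
        after_rows.append(spectrum(a, p.sample_id, "after_GD").proportions)
    return spectrum_ranksum_table(np.asarray(before_rows), np.asarray(after_rows))


def apobec_context_fraction(snvs: list[SomaticSNV]) -> float | None:
    """Fraction of C>T / C>G SNVs in TpCpW context (pyrimidine-oriented).

    None when no C>T/C>G SNVs are present. Raises when contexts are unset.
    """
    n_c = n_tcw = 0
    for v in snvs:
        cls = substitution_class(v.ref, v.alt)
        if cls not in ("C>T", "C>G"):
            continue
        if v.context is None:
            raise ValueError(f"SNV {v.chrom}:{v.pos}: trinucleotide context unset")
        ctx = v.context.upper()
        if len(ctx) != 3:
            raise ValueError(f"SNV {v.chrom}:{v.pos}: bad context {v.context!r}")
        if ctx[1] in "AG":  # reported on the purine strand; flip
            ctx = "".join(_COMPLEMENT[b] for b in reversed(ctx))
        n_c += 1
        if ctx[0] == "T" and ctx[2] in "AT":
            n_tcw += 1
    if n_c == 0:
        return None
    return n_tcw / n_c


def multiplicity_vs_cn(
    profile: TumorProfile, genes: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene (mutation multiplicity, covering-segment total CN) pairs.

    One row per mutated gene SNV with a set multiplicity; enables the
    oncogene-vs-TSG multiplicity comparison without applying labels.
    """
    rows = []
    for g in genes.itertuples(index=False):
        for v in profile.snvs:
            if v.chrom != str(g.chrom) or not (int(g.start) <= v.pos < int(g.end)):
                continue
            if v.multiplicity is None:
                continue
            seg = profile.segment_at(v.chrom, v.pos)
            if seg is None:
                continue
            rows.append(
                {
                    "sample": profile.sample_id,
                    "gene": str(g.gene),
                    "pos": v.pos,
                    "multiplicity": v.multiplicity,
                    "total_cn": seg.total,
                    "clonal": v.clonal,
                }
            )
    return pd.DataFrame(
        rows, columns=["sample", "gene", "pos", "multiplicity", "total_cn", "clonal"]
    )
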