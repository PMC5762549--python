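#!/usr/bin/env python
"""Compare mutational spectra before vs after GD and by clonality.

The before-GD stratum is clonal SNVs with multiplicity >= 2 inside 2:2
regions (they rode through the doubling); multiplicity-1 SNVs there postdate
it. Per-class rank-sum tests ask whether the doubling changed the spectrum,
and APOBEC TpCpW-context fractions are compared between clonal and subclonal
mutations.
"""

from pathlib import Path

import pandas as pd

from macroevo.core_io import read_arms
from macroevo.pipeline import load_cohort, stage_spectrum

COHORT = Path("results/analysis/cohort")
OUT = Path("results/analysis")

if __name__ == "__main__":
    arms = read_arms(COHORT / "arms.tsv")
    profiles = load_cohort(COHORT / "segments.tsv", COHORT / "samples.tsv", arms, COHORT / "snvs.tsv")
    gd = pd.read_csv(OUT / "gd.tsv", sep="\t").set_index("sample")["gd"]
    for p in profiles:
        p.gd_status = "GD" if bool(gd[p.sample_id]) else "NGD"

    df = stage_spectrum(profiles, arms, OUT)
    compare = pd.read_csv(OUT / "spectrum_gd_compare.tsv", sep="\t")
    print("spectrum before vs after GD (rank-sum p per class):")
    print(compare[["class", "mean_before", "mean_after", "p_value"]].round(3).to_string(index=False))
    n_sig = int((compare.p_value < 0.05 / 6).sum())
    if n_sig == 0:
        print("-> no class differs after Bonferroni correction: spectrum unchanged by GD")
    else:
        print(f"-> {n_sig} class(es) below the Bonferroni level in this cohort "
              "(the generator uses one spectrum for both strata, so treat as sampling noise)")
    clonal = df[df.stratum == "clonal"]
    sub = df[df.stratum == "subclonal"]
    print(f"APOBEC TCW fraction: clonal {pd.to_numeric(clonal.apobec_tcw_fraction).mean():.3f} "
          f"vs subclonal {pd.to_numeric(sub.apobec_tcw_fraction).mean():.3f}")
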