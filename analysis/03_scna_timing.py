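#!/usr/bin/env python
"""Classify focal SCNAs relative to GD and build gene score tracks.

Applies the parity rules (odd total/minor deletions and odd-change gains
postdate GD) to every focal deviation from the arm modal copy number, then
computes copy-number-altering scores and before-/after-GD event-set tracks
over a genome-tiling gene grid.
"""

from pathlib import Path

import pandas as pd

from macroevo.core_io import read_arms
from macroevo.pipeline import load_cohort, stage_scna, tile_genes
from macroevo.scna import focal_scnas

COHORT = Path("results/analysis/cohort")
OUT = Path("results/analysis")

if __name__ == "__main__":
    arms = read_arms(COHORT / "arms.tsv")
    profiles = load_cohort(COHORT / "segments.tsv", COHORT / "samples.tsv", arms, COHORT / "snvs.tsv")
    gd = pd.read_csv(OUT / "gd.tsv", sep="\t").set_index("sample")["gd"]
    for p in profiles:
        p.gd_status = "GD" if bool(gd[p.sample_id]) else "NGD"

    stage_scna(profiles, arms, tile_genes(arms), OUT)

    timings = [
        s.timing for p in profiles if p.gd_status == "GD" for s in focal_scnas(p, arms)
    ]
    counts = pd.Series(timings).value_counts()
    print("focal SCNA timing in GD tumors:")
    print(counts.to_string())
    print(f"score tracks written to {OUT}/event_set_tracks.tsv")
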