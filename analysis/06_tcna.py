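#!/usr/bin/env python
"""Deconstruct arm profiles into telomere-bounded copy-number steps.

Each copy-number change along an arm, read centromere to telomere, becomes
unit amplification/deletion events anchored at the breakpoint and extending
to the telomere. Reports the per-tumor burden and the most step-prone arms,
and checks the recovered steps against the planted truth.
"""

import collections
from pathlib import Path

import pandas as pd

from macroevo.core_io import read_arms
from macroevo.pipeline import load_cohort, stage_tcna

COHORT = Path("results/analysis/cohort")
OUT = Path("results/analysis")

if __name__ == "__main__":
    arms = read_arms(COHORT / "arms.tsv")
    profiles = load_cohort(COHORT / "segments.tsv", COHORT / "samples.tsv", arms, COHORT / "snvs.tsv")
    per_sample = stage_tcna(profiles, arms, OUT)
    print(f"TCNAs per tumor: min {per_sample.n_tcna.min()}, "
          f"mean {per_sample.n_tcna.mean():.1f}, max {per_sample.n_tcna.max()}")
    per_arm = pd.read_csv(OUT / "tcna_arms.tsv", sep="\t")
    per_arm["total"] = per_arm.amplification + per_arm.deletion
    print("most step-prone arms:")
    print(per_arm.nlargest(5, "total")[["arm", "amplification", "deletion"]].to_string(index=False))

    truth = pd.read_csv(COHORT / "truth" / "events.tsv", sep="\t")
    steps = truth[truth.kind == "TELOMERE_STEP"]
    events = pd.read_csv(OUT / "tcna_events.tsv", sep="\t")
    got = collections.Counter(zip(events["sample"], events.arm, events.breakpoint))
    want = collections.Counter(zip(steps["sample"], steps.arm, steps.breakpoint.astype(int)))
    hit = sum((got & want).values())
    print(f"planted telomere steps recovered at their breakpoints: {hit}/{sum(want.values())}")
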