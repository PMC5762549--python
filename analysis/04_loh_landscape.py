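#!/usr/bin/env python
"""Map the LOH landscape and split NLOH into GD-derived vs intrinsic.

Every minor=0 segment is an LOH event; in doubled genomes 2:0 states are
attributed to a pre-GD loss doubled by GD while 4:0 and odd-major states
need an intrinsic copy-neutral mechanism. Reports the intrinsic share and
the most recurrently affected arms.
"""

from pathlib import Path

import pandas as pd

from macroevo.core_io import read_arms
from macroevo.pipeline import load_cohort, stage_loh

COHORT = Path("results/analysis/cohort")
OUT = Path("results/analysis")

if __name__ == "__main__":
    arms = read_arms(COHORT / "arms.tsv")
    profiles = load_cohort(COHORT / "segments.tsv", COHORT / "samples.tsv", arms, COHORT / "snvs.tsv")
    gd = pd.read_csv(OUT / "gd.tsv", sep="\t").set_index("sample")["gd"]
    for p in profiles:
        p.gd_status = "GD" if bool(gd[p.sample_id]) else "NGD"

    samples = stage_loh(profiles, arms, OUT)
    events = pd.read_csv(OUT / "loh_events.tsv", sep="\t")
    nloh = events[events.category.isin(["NLOH", "amplified_LOH"])]
    print(f"{len(events)} LOH events across {len(profiles)} tumors; {len(nloh)} copy-neutral/amplified")
    print(f"intrinsic NLOH: {samples.intrinsic_event_fraction.mean():.0%} of events per tumor (mean)")
    top = pd.read_csv(OUT / "arm_loh.tsv", sep="\t").head(5)
    print("most affected arms (fraction of tumors with arm-level LOH):")
    print(top[["arm", "total"]].to_string(index=False))
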