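# macroevo

Macro-evolutionary analysis of tumor genomes: whole-genome-doubling (WGD)
detection and timing, parity-based timing of somatic copy-number alterations
(SCNAs), copy-neutral LOH (NLOH) classification, molecular-time estimation of
duplications from mutation multiplicities, and deconstruction of chromosome
arms into telomere-bounded copy-number alterations (TCNAs).

## Who this is for

Cancer-genomics analysts who already have allele-specific integer copy-number
segments (e.g. from a caller such as Patchwork/ASCAT), somatic SNVs with
variant allele fractions or multiplicities, and per-sample purity/ploidy, and
who want to reconstruct the *order* of macro-evolutionary events in each
tumor: did genome doubling precede or follow the bulk of losses, which focal
changes came before the doubling, when in molecular time did arms duplicate,
and how much of the karyotype was built by telomere-anchored steps. Because
cohorts with fully reusable allele-specific calls are rare, the package ships
a first-class synthetic-tumor generator that plants ground-truth event
histories with lineage-correct SNV multiplicities, so every estimator is
validated by parameter recovery.

## The models

**WGD detection.** A genome is called doubled when the length fraction of the
autosome with major allele copy number ≥ 2 is at least 0.5 and unreachable
(Monte Carlo p < 0.001, 100,000 simulations by default) under a null that
replays the sample's observed number of arm-level events as independent
single-allele arm gains on a diploid genome.

**GD vs losses.** Only losses to two total copies are informative: genotype
1:1 ("AB") requires losses after a doubling, 2:0 ("AA"/"BB") marks a loss
before it. Whichever genomic proportion dominates orders GD against the bulk
of losses; the statistic is `proportion(AB) − proportion(AA/BB)`.

**SCNA parity timing** (GD samples, total CN < 6): deletions with an odd
total or odd minor copy number postdate GD; other deletions predate it.
Gains with an even copy change Δ relative to the arm's modal CN predate GD;
odd Δ postdates it. The per-gene copy-number-altering score is k/n — the
fraction of samples with a segment spanning the gene midpoint that deviates
from its arm modal CN in the given direction — with ≥ 0.4 flagging frequent
alteration.

**Multiplicity clock.** With M_P the number of clonal SNVs at multiplicity P
in a region whose genotype occupies > 75% of its arm, the molecular time T of
a duplication is, by genotype:

| genotype | estimator |
|---|---|
| 2:0 | `T = M2 / (M2 + M1/2)` |
| 2:1 | `T = M2 / (M2 + (M1−M2)/3)` |
| 3:0 | `D = M3 + M2 + (M1−M2)/3; T1 = M3/D, T2 = (M3+M2)/D` |
| 4:0 | `D = M4 + M2/2 + M1/4; T1 = M4/D, T2 = (M4+M2/2)/D` |
| 2:2 (WGD) | `T = (M2/2) / (M2/2 + M1/4)` |

**NLOH partition.** In a doubled genome a 2:0 segment is exactly what one
pre-GD loss plus the doubling produces (GD-derived); 4:0 and odd-major LOH
states require an intrinsic copy-neutral mechanism (e.g. uniparental disomy),
and all NLOH in never-doubled genomes is intrinsic.

**TCNA deconstruction.** Reading each arm centromere → telomere, every copy
number change of ±k becomes k unit events anchored at the breakpoint and
extending to the telomere; the signed event sum always equals telomere CN −
centromere CN and the event count is the walk's total variation.

## Worked example

```bash
macroevo simulate --out cohort --seed 1
python analysis/01_simulate_cohort.py   # or the numbered analysis drivers
python analysis/02_genome_doubling.py
```

The numbered drivers under `analysis/` run the full study on a 20-sample
synthetic cohort (written to `results/analysis/`). Output from a run at seed
1:

```
simulated 20 tumors -> results/analysis/cohort
  18 genome-doubled (planted GD times 0.47-0.88), 2 non-doubled

GD calls agree with planted truth in 100% of 20 tumors
wGII: GD mean 0.292 vs NGD mean 0.276
100% of GD tumors classified GD-after-losses (AA/BB-dominated)

TCNAs per tumor: min 10, mean 16.0, max 20
planted telomere steps recovered at their breakpoints: 196/200

GD time estimated for 18 doubled tumors; mean |error| vs planted time = 0.007
```

Reading: the detector recovered every planted GD status; the loss-genotype
statistic classified all doubled tumors as GD-after-losses, matching the
planted histories in which most two-copy losses precede the doubling; the
multiplicity clock recovered the planted GD molecular times to within 0.007
on average; and the TCNA deconstruction recovered 98% of planted telomere
steps at their exact breakpoints (the remainder are steps whose copy change
was annulled by later overlapping events).

Each stage is also exposed on the CLI (`macroevo gd-call|scna-timing|loh|
clock|tcna|spectrum|run`) for cohorts supplied as TSVs: `segments.tsv`
(sample, chrom, start, end, major, minor; 1-based inclusive), `snvs.tsv`,
`samples.tsv` (id, purity, ploidy) and `arms.tsv`.

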