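# Methods

## Scope and data model

The package reconstructs the order of macro-evolutionary events in bulk tumor
genomes from three inputs it does not itself infer: allele-specific integer
copy-number segments (major/minor per interval), somatic SNVs with VAF and —
where available — multiplicity, cancer-cell fraction (CCF) and trinucleotide
context, and per-sample purity/ploidy. Purity/ploidy/CCF inference and
segmentation are upstream problems (callers such as ABSOLUTE and Patchwork
solve them) and are deliberately out of scope; a simplified multiplicity
estimator is provided for SNV tables that carry only VAFs.

Coordinates are 0-based half-open in memory and 1-based inclusive on disk
(the common SEG dialect); conversion happens only at the I/O boundary.
Segments straddling a centromere are split, never dropped, so every segment
maps to exactly one arm. Sex chromosomes are read but excluded from all
genome-wide statistics; "the genome" below always means the autosomes. A toy
arm map (22 chromosomes × 100 Mb, centromere at 40 Mb) ships for simulation
and testing; real assemblies are supplied as an `arms.tsv`.

## WGD detection and timing

Detection uses the major-allele-fraction test: the observed statistic is the
length fraction of the covered autosome with major copy number ≥ 2; a sample
is called doubled when this fraction is ≥ 0.5 **and** a Monte Carlo p-value
is < 0.001. The null model is fully specified here because the literature
behind the test leaves the simulation scheme open: the sample's number of
arm-level copy-number events (autosomal arms whose length-weighted modal
genotype deviates from 1:1) is replayed as that many independent
single-allele arm gains on a diploid genome, and p is the add-one estimator
`(1 + #{simulated fraction ≥ observed}) / (n_sims + 1)` with 100,000
simulations by default. Under this null a genuinely doubled genome (observed
fraction near 1 with ~44 arm events) is effectively unreachable, while
scattered gains are not, which reproduces the intended behavior of the test
while being reproducible from this document alone.

Timing against losses uses only total-copy-2 genotypes: 1:1 (both parental
alleles, "AB") can only arise by losing one copy of each allele after a
doubling, whereas 2:0 ("AA"/"BB") marks a single-allele loss before it.
Proportions are genomic lengths over the qualifying (AB + AA/BB) span; the
class is GD-before-losses when AB dominates, GD-after-losses when AA/BB
dominates, undefined on an exact tie or when no qualifying segment exists.
This genotype-only reading is the strongest statement bulk data supports —
no per-segment history is inferred.

wGII is the unweighted mean over covered autosomes of the per-chromosome
length fraction whose total CN differs from the sample's length-weighted
modal total CN; modal ties break toward the lower CN (conservative toward
calling less instability and non-doubled states).

## SCNA parity timing and the gene score

In doubled samples with segment total CN < 6, deletions with an odd total or
odd minor copy number must postdate the doubling (anything present before it
was doubled into even counts); other deletions predate it. Gains are timed
by the parity of the copy change Δ relative to the arm's length-weighted
modal total CN: even Δ predates GD, odd Δ postdates it. The rules assume
each focal SCNA is a single event — on the synthetic cohorts where that
assumption holds by construction, classification matches the planted labels
in 100% of applicable cases, which is the rule's ceiling, not a statement
about real mixed histories.

The copy-number-altering score of a gene in a direction (gain/loss) is k/n,
where a sample counts toward k when one segment spans the gene's midpoint
and deviates from its arm modal CN in that direction. "Covers the gene's
center" is read as midpoint containment — the simplest reading that avoids
fractional-overlap ambiguity. The frequent-alteration threshold is
inclusive (score ≥ 0.4). When a pre-/post-GD event-set filter is applied,
the covering segment must additionally be focal (< 75% of the arm) and total
CN < 6 so the parity rules apply; without a filter no focality constraint is
imposed.

## NLOH classification

Any segment with minor copy number 0 is an LOH event: 0:0 homozygous
deletion, 1:0 deletion-LOH, 2:0 NLOH, ≥3:0 amplified LOH. Adjacent events
with the same genotype on one arm are merged (length is conserved);
arm-level means merged length strictly greater than 0.75 of the arm. In
doubled samples, 2:0 is attributed to a pre-GD loss doubled by GD
(GD-derived); 4:0 needs a copy-neutral mechanism such as uniparental disomy
before the doubling, and odd-major states cannot arise from one loss plus
the doubling at all, so both are intrinsic. In never-doubled samples all
NLOH is intrinsic. The odd-major branch is the most assumption-laden: a 3:0
can also arise post-GD from a 2:0 plus a gain; the label records
"not explainable as loss+GD alone", which is what the intrinsic category
means here. Because it is unknown whether intrinsic burden is better
summarized by event count or genomic length, both are reported.

## The multiplicity clock

Molecular time is the fraction of total clonal point-mutation accumulation
(0 = initiation, 1 = sampling); the mutation rate is constant on this scale
by definition. A clonal mutation that predates a duplication is carried by
every copy descended from its lineage, so in a region of genotype (major,
minor) the multiplicity-class counts M_P have Poisson expectations that are
linear in the duplication time(s). Solving the moment equations gives the
closed forms (D is the implied per-lineage mutation total):

- 2:0 (loss then duplication): E[M2] = rT, E[M1] = 2r(1−T) ⇒ T = M2/(M2 + M1/2)
- 2:1 (duplication, other allele kept): T = M2/(M2 + (M1−M2)/3); the
  retained allele contributes M1 all along, hence the (M1−M2)/3 correction
- 3:0 (loss, then two sequential duplications at T1 ≤ T2):
  D = M3 + M2 + (M1−M2)/3, T1 = M3/D, T2 = (M3+M2)/D
- 4:0 (loss, then two rounds of doubling): D = M4 + M2/2 + M1/4,
  T1 = M4/D, T2 = (M4+M2/2)/D
- 2:2 (whole-genome doubling): T = (M2/2)/(M2/2 + M1/4)

Each form was re-derived from the lineage model and is gated by an
independent brute-force simulator (`macroevo.validation`) that builds the
case's lineage tree explicitly, drops per-branch Poisson mutations, and
counts multiplicities by descendant enumeration: mean absolute recovery
error is < 0.03 at ~2,000 mutations per region across planted times.

Numerical choices: only clonal SNVs are counted (subclonal mutations
postdate the clonal expansion and carry no timing signal for truncal
events); multiplicities above the genotype's major CN are dropped with a
warning; a negative (M1 − M2) — possible by sampling noise — is clipped to
zero with a warning rather than propagated as negative time; estimates are
clipped into [0, 1]; a zero denominator yields "undefined", not an error. A
region is timeable only when one genotype strictly exceeds 75% of its arm's
covered length (the arm mode); arms failing the rule are excluded. GD time
pools M1/M2 over all 2:2-mode arms genome-wide by default (per-arm estimates
are available), since pooling is the lower-variance choice when a single
genome-wide event is assumed. First-NLOH time is the minimum Case-1 estimate
over 2:0-mode arms. The gain-time summary reports min/median/span of per-arm
times and flags `punctuated` when ≥ 3 timed gains fall within a span ≤ 0.2 —
a documented heuristic for burst-like karyotype evolution, not a literature
rule.

## TCNA deconstruction

"Telomere-bounded" is judged against the centromere: an arm shows
telomere-bounded amplification (deletion) when its telomere-adjacent total
CN exceeds (falls below) its centromere-adjacent total CN; both arm ends
must be covered. Deconstruction walks the arm centromere → telomere and
emits |Δ| unit events of sign(Δ) at each boundary, each extending to the
telomere. This is the unique minimal set of telomere-anchored unit steps
reproducing the profile from the centromeric baseline (its size is the
walk's total variation), and re-applying the events reproduces the profile
exactly. Both unit-event counts and per-boundary grouped counts are
recoverable from the event table, since it is ambiguous whether a multi-copy
step should count once or |Δ| times. Coverage gaps are hard boundaries: each
covered block is deconstructed separately and all events on a gapped arm are
flagged `gapped`. Comparisons use total CN, not allele-specific CN.

## Mutation metrics

Multiplicity from VAF inverts `vaf = m·p / (p·CN_t + 2(1−p))` (p = purity,
CN_t = segment total CN) by rounding, clipped into [1, major]. On
noise-free simulator VAFs the inversion is exact at any purity; on real data
it is a stand-in for a full probabilistic caller. Clonality is `ccf ≥ 0.9`
(inclusive), a documented threshold standing in for a caller's probabilistic
assignment; it is echoed in output metadata. Spectra are six substitution
classes in pyrimidine orientation (purine-context SNVs are complemented) and
are invariant to strand reporting. The pre-/post-GD comparison strata are
clonal SNVs inside 2:2-mode regions with multiplicity ≥ 2 (unambiguously
pre-GD) versus multiplicity 1; other regions are excluded because parity
there does not separate the strata cleanly. The per-class test is a
two-sided rank-sum with tie-corrected normal approximation; on 1,000 null
simulations at n = 20 samples its type-I error is ≈ 0.05 (≤ 0.07), and a
planted C>T shift of 0.6 is detected at p < 0.01 in ≥ 95% of replicates.
The APOBEC statistic is the fraction of C>T/C>G SNVs in TpCpW context,
undefined (not zero) when the denominator is empty.

## The synthetic-tumor generator

The generator is the package's study cohort. Each sample receives an ordered
event history — arm-level losses, gains, uniparental disomies, telomere
steps at sub-arm breakpoints, and (with probability 0.8) a whole-genome
doubling drawn uniformly on molecular time [0.4, 0.9] — and the history is
realized as a per-region lineage forest: every genome copy is a tree node,
duplications split nodes, losses kill them, and GD splits every live node at
once. Clonal SNVs are laid down as a Poisson process along each surviving
branch (rate in SNVs/Mb/unit-time per copy; default 2.0, giving a realistic
~4/Mb diploid burden), and a mutation's multiplicity is the number of final
copies descended from its branch — so multiplicities are lineage-consistent
with the planted history by construction, which is exactly the assumption
the clock estimators make. Defaults (6 losses, 4 gains, 2 UPDs, 10 telomere
steps per genome; 7% subclonal SNVs with CCF uniform on [0.1, 0.6]; a
C>T-dominated spectrum with 30% APOBEC-context enrichment on C mutations)
emulate the profiled esophageal squamous-cell cohort: mostly doubled
genomes with late GD, 5–20 telomere-bounded steps per tumor, and a clonal
mutation majority.

What the generator does **not** emulate: sequencing noise in VAFs (VAFs are
model-exact; a purity < 1 mode exercises the multiplicity estimator but adds
no read sampling), multi-subclone phylogenies (one subclonal CCF pool, no
nested subclones), focal double-hit events inside one arm other than
telomere steps, and replication-timing or chromatin covariates of mutation
rate. Passing recovery tests therefore demonstrates estimator correctness
under the estimators' own model assumptions — not robustness to caller noise
on real data.

Event applicability is enforced at draw time (a loss needs a copy to lose; a
telomere deletion step must leave every telomeric region with at least one
copy, checked against the piecewise per-arm balance), with up to 100
re-targets per drawn event. Everything is reproducible: one integer seed
determines histories, realizations, and the emitted cohort files byte for
byte.

## Pipeline and problem sizes

`run_pipeline` chains simulate → gd → scna → loh → clock → tcna → spectrum
and writes per-stage TSVs, a per-sample summary, and a manifest carrying the
package version, seed, and every threshold (GD fraction 0.5, p 0.001, mode
fraction 0.75, score 0.4, arm-level 0.75, CCF 0.9, focal CN cap 6). Reruns
with the same config are byte-identical; the manifest contains no
timestamps for that reason. The shipped analysis uses a 20-sample cohort at
mutation rate 0.5 SNVs/Mb/time/copy (~2,500 SNVs per genome) and 10,000
Monte Carlo simulations per GD call in the drivers' validation runs — sizes
chosen so the full analysis and its replication run comfortably on a laptop
core; the library defaults remain 100,000 simulations and rate 2.0.

## Known limitations

- The NLOH mechanism labels are genotype-deductions, not inferences; mixed
  histories (e.g. post-GD gain on a GD-derived 2:0) are attributed to the
  intrinsic class by construction.
- The parity rules are undefined for total CN ≥ 6 (amplifications saturate
  parity information); such segments are reported as not-applicable.
- The clock assumes neutrality and a constant clonal mutation rate on the
  molecular-time scale; selection or rate shifts bias T toward the epoch
  with the higher rate.
- GD detection's null is a design choice (documented above); cohorts called
  with a different null may disagree near the decision boundary.
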