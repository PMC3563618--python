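# Methods

This note documents the statistical and numerical choices behind
`centomir`: what each stage assumes, which parameters matter, what the
synthetic-data generator does and does not emulate, and the known
limitations. No empirical claim here goes beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Preprocessing

Reads are processed in the order quality filter → 3′ adapter trim →
length filter → collapse.

* **Quality filter.** A read is discarded when more than `max_low`
  (default 3) base calls fall below `q_threshold` (default Phred 20;
  calls exactly at the threshold count as good). The count rule is the
  contract; the threshold itself is a common Illumina convention and is
  configurable. The filter sees the raw read including adapter bases —
  the two defensible orders (filter-then-trim vs trim-then-filter)
  differ only for reads whose low-quality calls sit in the adapter, and
  the chosen order keeps the accounting independent of trimming.
* **Adapter trimming.** The adapter prefix is slid left to right over
  the read; the first window with overlap ≥ `min_overlap` (6) and
  mismatch fraction ≤ `max_mismatch_rate` (0.10) wins, and the insert
  upstream of it is kept. Reads without a qualifying match are retained
  unchanged and flagged — they simply fail annotation later, which keeps
  the count-conservation invariant exact.
* **Length window.** 17–35 nt, the usual small-RNA gel-excision range,
  enforced computationally.
* **Collapsing** maps each distinct sequence to per-sample counts. It is
  a partition of surviving reads: per sample, tag counts sum exactly to
  the surviving-read count, and the result is independent of input
  order.

## IsomiR-aware quantification

Assignment is **exact lookup against an enumerated variant set**, not
alignment. For each reference mature sequence inside its precursor the
admissible variants are: 5′ trims/templated extensions within `window5`
(±2 nt), 3′ trims/templated extensions within `window3` (±3 nt), and at
most one non-templated 3′ base (any base differing from the precursor's
templated continuation), in combination. These windows cover the
terminal-modification variant classes that dominate observed isomiR
tables; internal mismatches make a tag unassigned (and thus a candidate
for novel discovery). When several modification paths produce the same
string (possible in repetitive contexts), the simplest label wins, with
a deterministic total order breaking ties. Tags admissible for several
miRNAs are counted once per matching miRNA and flagged ambiguous — a
documented policy choice, since multi-mapping resolution has no single
correct answer without genomic context.

Composition tables pool reads within each sample group:
`% variant v of miRNA m in group g = 100 · reads(m,v,g) / reads(m,g)`.
A miRNA with zero pooled reads in a group reports NaN, not 0 — absence
of evidence is not a 0 % composition. The dominant variant is flagged
per group because it frequently differs from the canonical reference.

## Differential expression

* **Normalization** divides each sample's counts by its total
  miRNA-assigned reads (times a scale, by default the mean library total
  so group means read like counts). This is total-count normalization;
  it assumes the groups have comparable global miRNA output and is
  subject to compositional effects (see generator notes below).
* **Expression filter**: keep miRNAs with count strictly > 10 in at
  least ⌈half the samples⌉. The strict inequality and the ≥-half rule
  are both contract-level choices; with 6 samples the boundary is
  exactly 3.
* **Test.** Per miRNA, pooled raw counts within each group form a 2×2
  table of miRNA reads vs all-other-miRNA reads. Pooling is required
  because Fisher's test needs integers and per-sample tables would be
  six tests, not one; it mirrors the library-level normalization logic.
  The two-sided p-value is the sum of the probabilities of all tables
  with the observed margins that are no more probable than the observed
  table. For table totals ≤ 2000 this sum is evaluated in exact integer
  arithmetic; larger tables use `scipy.stats.fisher_exact`, which
  implements the same convention (agreement verified to 1e-9 in the
  acceptance checks). Degenerate tables (an all-zero margin) return
  p = 1 and are flagged.
* **Multiplicity and calling.** Bonferroni over the m miRNAs actually
  tested (m is exposed in the output attributes for audit). A call
  requires adjusted p < α (0.05) and fold change > `min_fold` (2.0),
  where the fold is the ratio larger/smaller of the group mean
  normalized counts, with a 0.5 pseudocount only when one group mean is
  exactly zero. Results sort by direction, then descending fold.
* **Caveat.** Pooled Fisher's exact tests treat reads as the sampling
  unit and therefore ignore biological replicate variability; with deep
  libraries they produce extremely small p-values for modest
  differences. This matches the classical count-based recipe the
  package implements; dispersion-modelling DE is explicitly out of
  scope.

## Novel hairpin discovery

Candidates are unassigned tags with ≥ `min_reads` (10) total reads.
Mapping is exact substring search on both strands (minus-strand hits are
positions of the tag's reverse complement, reported in forward
coordinates). Around each mapped tag two 110-nt windows are excised —
tag on the 5′ arm (5 nt of 5′ flank) or on the 3′ arm — and the
better-folding window is kept; windows are truncated and flagged at
chromosome ends.

**Folding model.** Candidate windows are single stem-loops by
construction, so the model deliberately folds exactly one hairpin: a
dynamic program over closing pairs where E(i,j) is the minimum energy of
a stem-loop closed by (i,j), built either as a terminal hairpin loop
(≥ 3 unpaired bases) or from an inner pair with ≤ 6 unpaired bases per
side (stack if contiguous, bulge/internal-loop penalty otherwise). No
multiloops, no dangling ends, no coaxial stacking. Parameters:

* Watson–Crick stacks: the standard RNA nearest-neighbor table
  (−0.93 … −3.42 kcal/mol).
* GU wobble stacks: the typical tabulated wobble values, including the
  destabilizing tandem 5′GU/UG (+0.47). Early flat wobble averages let
  shuffled sequences chain short pseudo-stems below the acceptance
  threshold; the tabulated values are both more physical and more
  discriminating.
* Loop penalties: tabulated hairpin initiation (5.4–6.4 for loops of
  3–9, logarithmic extrapolation beyond), bulges 3.8/2.8/3.2… with
  logarithmic growth, internal loops 1.7 + 1.08·ln(t/2) plus an
  asymmetry penalty (0.5 per unpaired-base imbalance, capped at 3), and
  +0.5/+0.7 closure penalties per AU/GU pair closing a hairpin/internal
  loop.

The reported MFE is min(0, best); T and U are interchangeable. This is a
screening score for a fixed −25 kcal/mol threshold, not an RNAfold
replacement: absolute energies of complex structures will differ from
full Turner-model folds, but long near-perfect precursor stems score far
below −25 (typically −70 and below) while shuffled 110-mers centre
around −14 with ≈ 5 % crossing −25.

**Decision.** Accept iff MFE < −25 kcal/mol, GC fraction in
[0.25, 0.75], ≤ `max_loci` (5) genomic loci, and processing signature
≥ 0.8 (fraction of pooled reads at the locus whose 5′ ends agree within
±1 nt of the modal cut site — the operational form of Drosha/Dicer
precision). Scoring is a pure function of the criteria fields, so
re-scoring is idempotent. Homology to known precursors (edit-distance
identity via edlib) is reported but not gated, because a homology rule
cuts both ways — a minimum to look miRNA-like, or a maximum to be novel
— and that reading should be the user's.

In simulations, decoy loci (shuffled precursor sequences) are given
degradation-like read support with 5′ ends scattered over the locus, in
contrast to the precise cut sites of genuine hairpins: non-miRNA loci
lack Drosha/Dicer precision, and the signature criterion is designed to
capture exactly that. Decoy rejection therefore rests on both the fold
threshold and the signature; with fold alone ≈ 95 % of shuffled decoys
are rejected.

## Trajectory classification

Group contrasts use the two-sample Student's t-test (equal variances by
default; Welch optional). A p-value exactly equal to α counts as
significant, consistent with reporting practice that treats p = 0.05 as
a significant elderly-vs-longevity contrast. Degenerate zero-variance
equal-mean comparisons return p = 1.

`longevity_associated` requires (i) monotone control-bin means with a
significant youngest-vs-oldest-control contrast, (ii) no significant
difference between the longevity bin and the youngest bin, and (iii) a
significant difference between the longevity bin and at least one
intermediate elderly bin. `age_related` requires monotone means across
all bins including the oldest plus a significant youngest-vs-oldest
contrast. The two rule sets are mutually exclusive through the endpoint
contrast. Everything else is `none`. The trend test is the endpoint
contrast plus the monotonicity of group means — a deliberate
operationalization matching pairwise-t reporting, since no named trend
test is part of the contract.

A structural property worth knowing: condition (ii) tests an exact null
whenever youthful expression is perfectly preserved, so its pass rate is
1 − α by construction. Recovery of a planted longevity-associated mode
therefore cannot exceed 95 % in expectation at α = 0.05, whatever the
effect size or noise level; the acceptance report shows recovery
rates consistent with exactly this ceiling.

## Targets and enrichment

The seed is mature bases 2–8 (1-based; a 2–7 switch is provided, as both
conventions are in circulation), and a site is an exact DNA
reverse-complement match in the UTR; all (overlapping) positions count.
Genes with fewer than 2 sites are suppressed by default — the usual
stringency heuristic — and co-targeting by other panel miRNAs is
annotated because additive repression by several miRNAs is the
biologically interesting case. Enrichment is the one-sided
hypergeometric upper tail on the overlap between the target list and
each gene set (both intersected with the universe first), Bonferroni
over the number of sets. The module is a transparent surrogate operating
on user-supplied UTRs and GMT sets; conservation scoring and
multi-algorithm consensus prediction are out of scope.

## The synthetic-data generator

The generator emulates a two-group small-RNA study (default 3 vs 3
libraries) and a 4-bin cross-sectional age series (n = 5, 5, 5, 12).

* **Reference/genome.** Mature sequences of 20–23 nt embedded at offset
  5 of 110-nt precursors whose 3′ arm is the reverse complement of the
  5′ arm with two mutations, placed at non-overlapping loci on random
  strands of a synthetic chromosome. The base after the mature 3′ end is
  fixed to C so that A/T/G additions are guaranteed non-templated.
* **Abundances** are log-uniform over 10–10⁶, reproducing the
  multi-decade dynamic range of saturated miRNA sequencing. MiRNAs
  carrying planted fold changes may draw from a separate moderate range
  (`de_abundance_range`; the validation runs use 10⁴–2·10⁵), because
  differentially expressed miRNAs are characteristically of moderate
  abundance and planting a 5-fold change on the single most abundant
  miRNA would distort the whole composition.
* **Fold changes are planted on normalized read shares** — the quantity
  the pipeline estimates. A planted miRNA's expected share in its group
  is its baseline share times the fold; the compensating mass is spread
  proportionally over non-planted miRNAs (shares must sum to 1). The
  per-group sampling weights appear in the truth table and sum to 1
  exactly.
* **IsomiR mixtures** default to canonical 86.7 %, +A 9.3 %, +T 3.6 %,
  +G 0.4 % — a canonical-dominated profile with minor non-templated
  additions of the kind observed for highly expressed miRNAs.
* **Reads** are drawn multinomially over (miRNA, variant) categories,
  adapter-ligated, truncated/padded to the 36-nt instrument read length,
  with independent per-base substitution errors (default 10⁻³, no
  indels) and constant high-quality strings; an option injects k
  low-quality calls into a stated fraction of reads to exercise the
  quality filter. A count-level shortcut (`simulate_count_matrix`)
  skips read synthesis for experiments where sequence content is
  irrelevant (e.g. DE power runs).
* **Age series.** Pre-noise bin means: flat m; age-related
  m·(1+e)^i; longevity-associated m, m(1−e), m(1−e)², …, m (controls
  decline geometrically, the oldest bin returns to the youngest mean).
  Noise multiplies each individual's mean by 1 + N(0, σ), i.e. σ is a
  within-group CV.

**What the generator does not emulate:** ligation bias, PCR duplicates,
adapter dimers, indel errors, biological replicate overdispersion
(libraries are multinomial draws from their group's composition), other
small-RNA classes, and RNA editing beyond terminal additions. Passing
tests therefore demonstrate correctness of the algorithms under the
stated sampling model, not robustness to those real-data artifacts — in
particular, the pooled Fisher test's false-call rate under multinomial
nulls says nothing about its behaviour under biological overdispersion.

## Problem sizes and determinism

The validation suite runs at desk scale by design: ~10⁵ sequenced reads
for conservation and isomiR recovery, count-level 3-vs-3 experiments at
2·10⁶ reads/library with 324 miRNAs for DE (the study this emulates
sequenced ≈ 4.5·10⁶ reads per library), a 100-kb genome with 20 planted
hairpins and 40 shuffled decoys for discovery, and 200 replicates per
trajectory mode. All randomness flows from explicit integer seeds
through `numpy.random.default_rng`; a fixed seed reproduces FASTA/FASTQ
and all pipeline outputs byte for byte.
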