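# Methods

## The analysis model

The package treats cohort-level MSI analysis as five composable decisions.

**Locus discovery.** A microsatellite locus is a maximal tandem run of a
primitive motif (length 1–5 bp) with at least a configured number of full
copies: 10 for homopolymers, 5 for dinucleotides, 4 for units of 3–5 bp by
default. Coordinates are 0-based half-open everywhere except at VCF
boundaries (1-based, per that format). Motifs are stored canonically — the
lexicographically smallest rotation of the primitive unit — so the same
repeat read in any frame gets one identity, and a locus is keyed
cohort-wide as `chrom:start:motif`. Runs never cross an `N` (the repeat
count would be undefined). When candidate runs overlap, the longer total
run wins; ties prefer the smaller unit length (favoring informative
homopolymers), then the smaller start. Within a periodic region every
phase alignment of the repeat is a candidate, which matters when the
leftmost alignment collides with an adjacent locus. Only the reference
strand is scanned: the downstream tumor/normal comparison works on
repeat-length histograms and is strand-symmetric. Interrupted or imperfect
repeats and units longer than 5 bp are out of scope.

**Instability test.** At each locus a sample contributes two read
histograms over repeat copy-number, tumor and normal. These are compared
with a Pearson chi-square homogeneity test on the 2 × K table over the
union of observed repeat lengths. Columns whose minimum expected count
falls below 5 are pooled into the adjacent column with the smaller total
(left on ties) — pooling depends only on column totals, so the test stays
symmetric under swapping tumor and normal; if a single column remains the
locus is untestable and p = 1. Loci where either tissue has fewer than
`min_cov = 20` reads are reported stable with p = 1 ("insufficient
coverage") — 20 keeps expected counts in the range where the chi-square
approximation holds. Simulated null tables at coverage 100 with the
default stutter kernel put the empirical size at ≈ 0.050 for α = 0.05.
Direction is deliberately not inferred: instability is presence/absence of
a distributional difference. There is no tumor-only mode; a matched normal
is required.

**Multiple testing.** Within a sample, significance is decided on
Benjamini–Hochberg-adjusted p-values across that sample's testable loci
(default), with raw per-locus thresholding available via `fdr=None`. A
genome is microsatellite-stable when *no* locus is called; with hundreds
of loci per exome, raw α = 0.05 thresholding would give essentially every
stable genome a handful of false calls (P(≥1 false call) ≈ 1 across ~360
loci) and make the MSS category unreachable, which is also why MSI callers
in the field FDR-correct. The per-locus test itself remains uncorrected
and calibrated (see above); only the call set is adjusted.

**Consensus and TMB.** Somatic variants count only when at least 2 of 3
callers report the same normalized key (chromosome, position, minimal
left-aligned alleles) — genotype and quality fields are ignored, because
the vote is defined at the site/allele level; multi-allelic records are
split before normalization. Whether callers should be compared on raw or
normalized representations is an open choice; this package normalizes
first, since identical edits spelled differently by different callers are
the main failure mode a vote must survive. Panel-of-Normals filtering is
exact-key set difference (no positional fuzz, for determinism). TMB is
coding consensus mutations (nonsynonymous + synonymous, including coding
indels; a switch restricts to nonsynonymous) outside the mitochondrial and
unplaced contigs, divided by the exome target size, 57 Mb by default.
Effect classes are read from an input annotation (VCF `EFFECT` tag);
functional annotation itself is out of scope.

**Burden and classification.** Per-locus calls are filtered to loci
unstable in at least `min_samples = 5` distinct samples — the recurrent
panel; support counts samples, not events, and a configurable histotype
list (default empty) can be excluded from support counting when one
histotype's event load would swamp the filter, while its samples still
receive scores against the final panel. A sample's MSI burden is the
fraction of panel loci unstable in it. Categories: MSS iff the sample has
zero unstable loci anywhere; EXCLUDED iff it has events but none on the
panel (patient-specific only) — a first-class output category rather than
a silent drop, so the classified subset stays auditable; otherwise MSI-H
when burden exceeds the cohort mean and MSI-L when at or below it (ties go
to MSI-L: "above the mean" is strict). The mean is taken over classifiable
samples (≥ 1 panel locus) by default; `threshold_population="all"`
averages over everyone instead. Averaging over classifiable samples is the
default because a zero-inflated mean would mostly measure the MSS fraction
rather than locate a cut within the burden distribution.

**Statistics.** Category comparisons use the unpaired two-sample
Mann–Whitney rank-sum test, two-sided: exact null distribution when both
groups have ≤ 25 observations and no ties, normal approximation with tie
and continuity correction otherwise. Quartiles use type-7 linear
interpolation (the default of mainstream statistical environments). The
burden–TMB association reports Pearson r with its t-test p-value, the OLS
slope/intercept of TMB on burden, and R² = r² — both r and R² are printed
because summary correlations in the literature are often ambiguous between
them. No multiple-testing correction is applied across the three pairwise
category tests (the flat p ≤ 0.05 rule is the convention this analysis
follows); EXCLUDED samples take part in no comparison, which the report
states.

## The synthetic cohort

The generator provides planted ground truth for every stage. Defaults are
fixed once and describe the study conditions:

* **Cohort template**: ten histotypes with sizes proportional to
  137 : 136 : 103 : 98 : 65 : 64 : 52 : 28 : 5 : 4 (a 692-sample canine
  pan-cancer cohort at scale 1.0; the desk-scale default is 0.2 → 139
  samples).
* **Instability rates** per panel locus span orders of magnitude:
  0.19 for the B-cell-lymphoma-like histotype down to 0.001 for the
  T-cell-lymphoma-like one, mid histotypes 0.03–0.06. The highest and
  lowest rates mirror the extremes reported for canine cohorts; the mid
  rates are set so that the k = 5 recurrence filter remains satisfiable at
  desk scale (expected per-locus support ≈ 13 samples) — with mid rates an
  order of magnitude lower, k = 5 is only reachable at the full n ≈ 692.
  Background loci acquire patient-specific events at ~0.002 per locus.
* **Reference**: each planted locus is a motif from a fixed pool with
  10–16 (mono), 6–12 (di) or 4–9 (tri/tetra) copies, separated by 30 bp
  repeat-free flanks whose junction bases cannot extend a planted run;
  each chromosome is rebuilt until the scanner recovers the plant exactly,
  so the site list is ground truth by construction.
* **Read model**: coverage ~ Poisson(100) per locus and tissue; histograms
  are multinomial around the true repeat count with a symmetric ±1 stutter
  kernel (0.1 per side), mimicking PCR/sequencing stutter; unstable tumor
  loci shift the center by 3 repeats (deletion-like, floored at 1).
* **TMB coupling**: `TMB = 0.5 + 8 × burden + N(0, 0.25²)`, truncated at
  0 and realised as a coding-mutation count over 57 Mb. These values put
  stable samples near TMB ≈ 0.5 and high-burden samples near ≈ 2, matching
  the magnitudes seen in real canine cohorts, and imply a closed-form
  target correlation r = 8σ_b / √(64σ_b² + 0.0625) that the statistics
  module must recover.
* **Callers**: each true variant enters each caller independently with
  sensitivity 0.95 (0.9 in the closed-form recall check, where expected
  2-of-3 recall is 3·0.9²·0.1 + 0.9³ = 0.972); private false positives at
  0.02 per true variant; half of all artifacts are also placed in the PON.

What the generator does **not** emulate: read-level data (FASTQ/BAM),
alignment and recalibration artifacts, realistic mutational signatures,
locus-specific stutter profiles, tumor purity/subclonality (unstable loci
shift fully rather than partially), breed or population structure, and
caller-specific error modes beyond flat sensitivity/false-positive rates.
Passing tests therefore demonstrate the correctness and calibration of the
statistical machinery on data with the assumed structure — not performance
on real exomes, where purity, stutter heterogeneity and mapping artifacts
dominate.

## Numerical and design notes

* Problem sizes in tests and the acceptance script: 500 random sequences
  (≤ 2 kb) for the scanner oracle, 10,000 null loci for calibration, 1,000
  random call-sets plus ≥ 10,000 true variants for the consensus checks,
  10 seeds of the 139-sample default cohort for full-pipeline recovery,
  n = 500 cohorts for the correlation target, 300 seeds for power/size of
  the rank-sum comparison (two groups of 30, shift 0.86 · sd, calibrated
  to ≈ 0.9 power at α = 0.05).
* Degenerate inputs: an all-stable cohort classifies everyone MSS with no
  threshold (reported as null); an empty recurrent panel is an error for
  burden computation and a named pipeline failure; a constant burden or
  TMB vector makes the correlation "not-computable" rather than an
  exception, as does an empty category in a pairwise test.
* Determinism: a fixed generator seed yields byte-identical FASTA/TSV/JSON
  outputs; the pipeline embeds SHA-256 checksums of its stage artifacts in
  the report, and reruns on identical inputs reproduce them.
* Known limitations: per-locus agreement with any specific external MSI
  caller is not claimed (coverage cutoffs and FDR settings of such tools
  vary); the scanner is tested to 2 kb sequences and desk-scale references,
  not whole genomes; the left-aligner requires a reference base accessor
  and otherwise only trims.
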