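# Methods

This note records the measurement conventions, model assumptions and
numerical choices behind `poreprof`, in the order the pipeline applies
them.

## Dual-strand alignment reconstruction

Error labels are only meaningful in sequencing orientation: if a
reverse-strand read is reverse-complemented before alignment (the usual
aligner shortcut), every substitution label is complemented and the flanks
of every error are mirrored. The pipeline therefore consumes two alignment
files per run — reads vs the forward genome *G* and reads vs rev(*G*),
both produced with read reverse-complementing disabled — and reconstructs
per-column alignments from CIGAR against the oriented genome copy
(M/=/X consume both sequences; I consumes the read; D/N consume the
reference; S/H are recorded as clip lengths, both counting toward the
original read length).

For each read the alignment with the lower global error rate is kept,
ties broken toward the forward orientation. The aligner's own score is
deliberately not used: it is aligner-specific and not always preserved in
SAM, whereas the error rate is the quantity under study and makes the
selection reproducible across aligners. Reads whose clipped length
exceeds half the read are discarded, since their error rate would
describe only the fragment the aligner chose to keep.

Internal coordinates are 0-based half-open; reads aligned to rev(*G*)
keep oriented coordinates internally, and a position *p* maps to
*L* − 1 − *p* on the forward genome for genome-anchored aggregation.
Columns pairing an N with anything are counted in the alignment length
but treated as neither match nor mismatch (no defined base identity) and
are excluded from substitution matrices.

## Error decomposition

Rates are ratios of error columns over total alignment length. Indel runs
count column-wise: a 3-base deletion contributes 3 deletion errors. An
insertion column is anchored to the preceding reference base (leftmost
convention; insertions before the first aligned base anchor to the
alignment start). Two aggregation modes exist and are both exposed,
because they answer different questions: pooled column counts (run-level
rates, used for global summaries) and unweighted means of per-read rates
(used for per-read binned figures such as error vs read GC).

The transition/transversion comparison uses the read as the sampling
unit: per read, the A↔G (resp. C↔T) substitution fraction divided by its
2 pairs is compared to the transversion fraction divided by its 8 pairs,
with a Welch two-sample t-test. The per-pair normalisation makes
"substitutions uniform over the 12 pairs" the null hypothesis of the
test; without it the comparison would be structurally biased 2:1 even for
pair-uniform errors.

## Quality model

Phred semantics: *P* = 10^(−*Q*/10). Windows of 100 read bases slide
along each read (default stride 25 bases — full base-by-base sliding is
available but changes bin means only marginally at 4× the cost); deletion
columns strictly between a window's first and last read base contribute
to its error count and alignment length but carry no quality. Mean window
quality is the arithmetic mean of per-base Phred values rounded to 0.1;
an alternative probability-domain read mean (−10·log₁₀ of the mean error
probability, the convention of basecaller read-level scores) is available
where a per-read quality is needed. The quadratic quality→error model is
fitted by weighted least squares (weights = bin supports) on the percent
scale over a configurable quality range (default [7, 30]).

Read retention by threshold reports, for each mean-quality cutoff, the
kept fraction relative to the lowest threshold and the mean error of kept
reads; the pipeline excludes reads below a mean quality of 10 from
analyses (the stricter of the two common cutoffs) while keeping them in
the retention report.

## Low-complexity repeats

Definitions on the reference, forward strand (and, for assessment, on
each oriented genome copy so reverse-strand reads are scored against the
repeat as sequenced): homopolymer = maximal run of k ≥ 2 identical bases;
heteropolymer = k ≥ 2 copies of a two-base unit XY (X ≠ Y), length 2k,
with a trailing odd base excluded (ACACA counts as AC×2); trinucleotide
repeat = k ≥ 2 copies of XYZ excluding pure single-base units, reported
per phase (overlapping occurrences of different motifs are all reported,
as each is a distinct repeat a read can fail). Symmetric dinucleotides
(AC/CA) pool in genomic distributions; trinucleotides group by strong
(C/G) vs weak (A/T) composition: S-only, mostly-S, mostly-W, W-only.

A read is assessed against an occurrence only when its aligned span
covers it entirely. The observed homopolymer length is the maximal run of
the motif base in the read overlapping the aligned interval. This
run-based gauge deliberately absorbs the aligner's freedom in gap
placement: an insertion of the motif base at either repeat boundary
extends the measured run no matter which column the aligner chose for the
gap. "Correct" means the rendered segment is exactly the motif repeated
the reference number of times with nothing else inside and no same-base
extension beyond it. For heteropolymers and trinucleotides the exact-match
rule is analogous and the observed length is the longest tandem
repetition of the motif in the rendered segment, in motif units × unit
length.

For the H/A attribution (errors in homopolymeric regions over all
errors), mismatches and deletions are attributed by their anchored
reference base; insertions are attributed when anchored strictly inside
or at either boundary base of a run — the boundary convention again
reflects gap-placement ambiguity at run edges.

## Perfect and harmful k-mers

The longest perfect k-mer of a read is its longest run of strict match
columns. Distribution summaries use sample standard deviation (ddof 1)
and a histogram mode of bin width 1 with smallest-value tie-break;
Pearson skewness coefficients are SCP_mode = (mean − mode)/sd and
SCP_median = 3(mean − median)/sd, flagged undefined when sd = 0. The seed
size at confidence c is the largest k such that at least a fraction c of
reads contain a perfect stretch of ≥ k bases (floor convention on the
empirical quantile).

Harmful k-mer contexts are taken from the read (reference-context mode is
available), k read bases immediately before or after the error site,
skipping gap columns; for deletions the context is the flanking read
bases around the gap, and consecutive indel columns form a single
context-extraction site so one gap event yields one context (each column
still counts individually as an error elsewhere). Contexts truncated by
read ends are skipped. Events anchored in homopolymer runs can be
excluded to separate sequence-specific effects from the dominant
homopolymer effect. Top-N tables per dataset merge across datasets with
per-GC-class tallies.

The automaton over the retained k-mers is the minimal deterministic
layered letter-graph: prefixes with identical residual suffix sets
(right languages) share a state, edges carry supporting k-mer counts per
GC class, and before pruning the edge weights entering each layer sum to
the total k-mer weight. Pruning (default: nodes with total incoming
weight < 4) is a display/export convention; the full automaton is kept
internally.

## Signal analysis

The module consumes a resquiggler-style event table (read, forward
reference position, raw-signal sample count; sampling rate default
4000 samples/s) and computes translocation speed *S* = *N*/*E* × *R*.
Error-vs-speed profiles tile each read's reference span into 25-base
windows (reference-anchored: deleted bases count toward *N* although they
carry no read base, since the molecule still traversed the pore);
windows without complete event coverage are skipped; speeds bin at
50 bases/s.

## Synthetic generator

The generator emulates the biases the analyses measure, under an
analyzable generative model:

* **Background errors** are i.i.d. per column: substitution 0.02,
  insertion 0.015, deletion 0.025 per column by default (≈6% total, the
  raw-accuracy regime of current chemistry, deletions dominant).
  Substitution targets follow a transition multiplier (default 4, within
  the 3–5× range the substitution analyses detect).
* **Per-read variation**: a lognormal rate multiplier (σ = 0.35,
  mean-preserving) reproduces the broad per-read quality spread; a small
  per-base lognormal jitter (σ = 0.1) decorrelates adjacent bases.
* **GC coupling**: the total rate gains 0.0004 per GC-percent deviation
  of the read from 50%; references are generated with block-wise GC
  variation (20 kb blocks, σ = 0.08) so reads sample a realistic GC
  spread. The default reference GC is 0.50, the neutral midpoint between
  the low- and high-GC regimes.
* **Homopolymer length model**: runs of length ℓ ≥ 5 override the
  background: no background errors occur inside them or at their
  single-base flanks, and the rendered length is ℓ + δ with
  P(δ = 0) = exp(−0.3·(ℓ − 4)) — about 74% exact at ℓ = 5 and 30% at
  ℓ = 8, matching the observed decay shape — where nonzero δ is negative
  with probability 0.8 (1 + Poisson magnitude growing with ℓ, capped at
  ℓ) and otherwise a geometric overshoot (the long-insertion tail).
  Because such runs cover well under 1% of a typical genome, realized
  genome-wide rates stay at the nominal values; shorter homopolymers keep
  ordinary background errors, as in real data. The analytic curve is
  exposed (`homopolymer_correctness_curve`) and is exact for ℓ ≥ 5 by
  construction, which is what the recovery tests check; below the
  threshold accuracy is governed by background errors and is only checked
  qualitatively (higher than any model-governed length).
* **Qualities** encode the expected per-*column* error probability of the
  background model — total per-base probability diluted by the insertion
  columns, p/(1 + p_ins) — which is exactly what alignment-based error
  measurement estimates, so the identity quality model reproduces the
  Phred line. FASTQ restricts qualities to integer Phred values; with a
  continuous read-quality distribution this quantization biases per-bin
  means by ~1–3% relative (band averaging), so calibration fixtures use
  the `quality_grid` option, which snaps each read's expected column rate
  onto the integer-Phred grid and makes the identity emission exact. A
  constant `quality_offset` (e.g. +5) produces the overestimated-quality
  signature: observed error above the Phred expectation at every reported
  quality.
* **Events**: per-base sample counts are Poisson around
  4000/450 ≈ 8.9 samples/base; deleted stretches are thinned by the speed
  coupling factor (default 2×), reproducing the fast-translocation signal
  of deletions.
* **Protocol fidelity**: reads are drawn from both strands uniformly and
  emitted in sequencing orientation against the corresponding oriented
  genome copy in two SAM files, with correct CIGARs; optional fixed soft
  clips, 5mC-style modification calls on read C bases, and exact truth
  tables (per-read error counts; per-homopolymer rendered lengths for
  model-governed runs, computed by an independent string-scan of the
  emitted read).

Read lengths default to lognormal with median 10 kb truncated to
[0.5, 100] kb, mirroring typical MinION runs. Fixed seeds reproduce every
output byte-for-byte.

What the generator does **not** emulate: pore physics and k-mer-dependent
signal levels, basecaller-specific artifacts (quality dips at read ends,
GC-dependent quality discontinuities), chimeric or adapter sequence,
non-uniform coverage biases, or any organism's real k-mer spectrum.
Passing recovery tests therefore demonstrates that the measurement code
is correct and unbiased under a known generative model — not that real
runs will show these exact numbers.

## Problem sizes and tolerances

The recovery suite uses a 5 Mb reference at ~30X (≈150 Mb of alignment,
the scale at which pooled rates are stable to ±0.002 and homopolymer
strata up to length ~10 retain ≥500 assessments); the acceptance script
uses 2 Mb at ~12X for the same statistics plus a 150 kb run with event
tables for the speed analyses, and quality-calibration fixtures of 800 ×
2 kb reads. Statistical checks use 3 standard errors per bin against
closed-form expectations, with non-overlapping windows where the
empirical standard error must be exact, and family-wise allowances where
many bins are tested jointly. Oracle checks (column classification,
repeat detection, longest perfect run) compare vectorised implementations
against independent brute-force scans on 1000 random instances each.

## Known limitations

* "Best alignment" selection by error rate can differ from the aligner's
  own ranking for near-tied multi-mapping reads.
* Observed repeat lengths use the run-based gauge above; conventions that
  freeze the aligner's gap placement would count boundary insertions
  differently (a bare "same base, same length" correctness rule leaves
  this gauge free).
* Read GC is computed on aligned read bases (clips carry no alignment),
  which slightly attenuates GC-error slopes relative to whole-read GC.
* The t-test unit (the read) makes the transition tests sensitive to the
  read count, as in the source analyses; effect sizes, not p-values, are
  comparable across runs.
* Region-stratified rates and modification stratification trust the
  caller-supplied BED/TSV coordinates; no liftover or validation beyond
  bounds checks is performed.
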