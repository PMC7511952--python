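# Methods

## Scope and model

The package implements a predictive-marker workflow for neoadjuvant
therapy of HER2-positive breast cancer.  The outcome label is
pathological complete response (pCR), a binary per-patient variable.
Three fixed, disjoint cohorts — screening, validation, re-validation —
are declared in the sample sheet and never recomputed; genome-wide assays
(methylation array, expression array, targeted tumor/normal sequencing)
belong to the screening set, while held-out cohorts contribute only
locus-level measurements of candidate markers.  This mirrors the
discover → confirm → re-confirm design of marker studies and is enforced
in code: screening statistics read only screening-set columns (a property
the test suite checks by mutating held-out data).

## Stage models and parameters

### Somatic variant filter

A call passes iff all six hold: tumor VAF > 0.10; normal VAF < 0.01;
homopolymer length < 3; ≥ 5 alt reads on *each* strand; coverage > 100;
consequence ∈ {missense, nonsense, frameshift, splice}.  Strictness
follows the rule wording literally and is pinned by boundary tests
(coverage 100 fails, 101 passes; VAF 0.10 fails, 0.101 passes, …).  The
strand rule is ambiguous in common usage ("found in both strands in 5
reads or more"); the per-strand reading is the default and a
total-with-both-strands-represented reading is selectable
(`strand_rule="total"`).  The filter is a pure monotone predicate:
weakening any evidence field can never turn a failing call into a passing
one (property-tested).

### Copy number

Region depths are normalized to depth fractions (depth / total reads per
sample) and the tumor/normal ratio of fractions is the fold change; gain
iff fold > 2, loss iff fold < 0.5, both strict.  A region with tumor
signal but zero normal depth is an unbounded gain (fold = ∞); a region
silent in both samples is neutral with undefined fold.  No segmentation
or genotyping is attempted — inputs are pre-summarized panel depths.

### Expression

Raw intensities are log₂-transformed and shifted per sample so the 75th
percentile of all probes is exactly 0 (numpy linear-interpolation
percentile; the rule is pinned by a hand-computed unit test).  This makes
the transform idempotent under re-normalization and invariant to
per-sample multiplicative rescaling.  The volcano screen tests each gene
between outcome groups; the differential test behind published volcano
screens of this kind is rarely stated, so the default is Welch's t-test
with Mann–Whitney selectable — gene lists can differ by test choice, and
the choice is recorded in the run manifest.  Selection requires p < 0.001
and linear fold change > 4; no multiple-testing correction is applied,
matching the raw-p gate convention of such screens.  "Average intensity"
for the abundance gate (> 0.5) is the grand mean of normalized log₂
intensity over all screening samples.

### Methylation screen

β ∈ [0, 1] is the per-CpG methylation fraction; missing β is a validation
error (missingness handling is deliberately out of scope in v1).  The
screen:

1. keeps probes with β < 0.2 (strict) in *every* normal reference profile
   (mammary epithelial plus leukocyte profiles), restricting candidates
   to cancer-specific methylation gains;
2. calls a sample methylated at a probe iff β > 0.3 (strict; β = 0.3 is
   unmethylated);
3. evaluates, per probe and per direction (hyper-in-pCR /
   hyper-in-non-pCR), the accuracy and specificity of "methylated ⇒
   predicted member of that direction's group".  Specificity is computed
   on the direction's negative class — the only orientation under which
   both directions face the same gates symmetrically.  A site passes at
   accuracy > 0.67 and specificity > 0.85; if both directions pass (a
   degenerate small-n case) the higher-accuracy direction is kept, ties
   going to hyper-in-pCR;
4. keeps CpG-island and genic sites, then emits a marker region for every
   maximal run of ≥ 3 passing probes that are adjacent in the annotated
   region's complete position-ordered probe list and share a direction.
   "Consecutive" therefore means no intervening non-passing probe of the
   same region; `max_gap` (default 0) optionally allows bridging.

Candidates are confirmed on the validation cohort and, if significant
(Mann–Whitney p < 0.05 on region-mean β, emulating a locus assay), on the
re-validation cohort.

### Performance evaluation

All contingency work fixes: positive class = pCR, marker-positive =
predicted pCR.  Metrics are exact count ratios; a metric with a zero
denominator is `None`, never 0.  Rendered percentages are one decimal,
round-half-up on the exact rational (so 40/128 → 31.3).  Age strata <45 /
45–55 (inclusive both ends) / >55 partition all ages, so stratum counts
sum to the overall table (tested).  The dichotomization cutoff for
continuous methylation levels has **no default**: a clinically meaningful
cutoff must come from calibration data, so the pipeline refuses to run
the performance stage without an explicit value (examples use 0.15 as an
explicitly non-canonical placeholder).

### Response monitoring

Δβ defaults to absolute percentage points, (baseline − on-treatment) × 100:
since β is itself a fraction, a "Δβ ≥ 50%" rule most plausibly means a
0.5 drop in β.  Relative-to-baseline is selectable and both can be
reported, keeping the ambiguity visible.  The large-decrease comparison
is ≥ (inclusive), with a 1e-12 relative tolerance so a drop equal to the
threshold in exact arithmetic is not lost to floating-point subtraction.
Paired shifts use the Wilcoxon signed-rank test: zero differences are
dropped (standard practice; all-zero input degenerates to p = 1 with a
warning); for n ≤ 15 the two-sided p is exact by enumeration of all 2ⁿ
sign assignments using midranks of |d| (so tied magnitudes are exact),
above that the tie-corrected normal approximation with continuity
correction.  Marker comparison reports, per marker and outcome group, the
fraction of samples with any decrease and with a large decrease; a marker
that falls in everyone (Ki-67-like) shows high consistency in both groups
and hence no discriminative value.

### Statistical tests

Fisher's exact test (two-sided, sum of hypergeometric probabilities of
tables at least as extreme) and the Mann–Whitney U test go through
scipy.stats; Mann–Whitney is exact (assignment enumeration) when both
groups have ≤ 10 observations and no ties, otherwise tie-corrected
asymptotic with continuity correction.  The test suite checks all three
tests against independent enumeration oracles (hypergeometric pmf sums,
permutation and sign-vector enumeration) written from the definitions.

## Synthetic data: what it emulates and what it does not

`simulate_cohort` produces one deterministic bundle per seed (a single
`SeedSequence` spawns one child stream per data layer, so layers are
individually reproducible).  Defaults are the study conditions: screening
14 pCR / 20 non-pCR, validation 17/30, re-validation 17/38; 10,000 array
probes in 5-probe annotated regions; 2,000 genes with 10 planted
differentially expressed genes at log₂FC 2.5, per-sample noise SD 0.3;
ER-negative prevalence 0.8 in responders and 0.35 in non-responders;
on-treatment marker decay of 80% in responders.

β-values come from a two-component Beta mixture — background mean 0.05
and methylated mean 0.6 at concentration 20 (reference profiles use
concentration 100, reflecting clean normal tissue) — chosen to straddle
the screen's 0.2/0.3 thresholds; no distributional model is implied by
the thresholds themselves.  Draws are clipped to [0, 1] after noise
rather than truncated-sampled; any bias is irrelevant to threshold logic.
One CpG-island region of 4 consecutive probes carries the planted marker:
a sample is methylated across the whole region with probability 0.8
(responders) or 0.02 (non-responders).  The non-responder prevalence is a
calibrated choice: the specificity gate (> 0.85 over 20 non-pCR samples)
tolerates at most 2 methylated non-responders, and P(Binom(20, p) ≤ 2) is
0.99 at p = 0.02 but only 0.68 at p = 0.10 — a 10% background prevalence
would make recovery of a genuinely planted marker a coin flip, which is
not a useful test condition.

The generator does **not** emulate Infinium type-I/type-II probe
chemistry, batch effects, cellularity/purity variation, β missingness, or
correlated probe noise within regions.  Passing tests therefore show that
the screening *logic* behaves as specified under its stated statistical
assumptions — not that the thresholds are optimal for, or robust on, real
array data.

## Numerical and design choices

* Percent rendering uses `Decimal` on exact counts (round-half-up, 1 dp);
  tests compare exact ratios, never rendered strings.
* Coordinates are 1-based; consecutive-probe ordering sorts by
  (chromosome, position) within the annotated region.
* File round-trips are lossless: writers use 17-significant-digit floats
  and readers parse with round-trip precision.
* The pipeline writes a manifest (config, config hash, package version)
  and a per-stage funnel audit (counts in/out of every filter); identical
  config + inputs give byte-identical outputs.
* Genome-wide counts from any real study (universe sizes, site counts,
  mutation totals) depend on that study's arrays and are not reproduced
  here; the funnel audit plus boundary/oracle/recovery tests are the
  desk-scale substitute.

## Problem sizes

Default test and acceptance runs use the full default generator (10,004
probes × 136 samples) — the screen is vectorised and a 20-replicate
recovery experiment completes in a few seconds.  Pipeline-level tests use
a 1,000-probe bundle, a size chosen because it exercises every code path
with sub-second runs.

## Known limitations

* Single-marker performance only: no multivariable modeling, survival
  analysis, or cutoff calibration.
* VCF input is limited to pre-summarized fields; no pileup or genotyping.
* The validation stage confirms candidates one region at a time with raw
  p-values, mirroring the workflow it models; it does not correct for the
  number of candidates carried forward.
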