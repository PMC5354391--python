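# Methods

## Coordinate model and inputs

All coordinates are 0-based half-open (BED convention); writers emit
BED/bedGraph accordingly. The unit of input is a per-sample set of
non-overlapping scored domains: intervals plus a mean read count per
nucleotide, as produced by an HMM broad-domain caller. The score column
of such files is configurable (`score_column`, default 5) because
deposited layouts vary. Domains with zero depth are kept — they
contribute nothing to scores but keep base-pair accounting exact.
Alignability *deadzones* are subtracted from every dataset (sample
domains and feature tracks alike) before binning; a window is masked
exactly when it has no non-deadzone nucleotide. No coverage threshold
beyond that is applied.

## Window scoring

A window's raw score is Σ over domains of `mean_depth · |(domain \
deadzones) ∩ window|`, in read-count·bp. The score is deliberately the
raw sum rather than a per-bp density: the subsequent mean-normalization
cancels any constant factor, truncated terminal windows then carry
proportionally smaller raw scores (matching the nucleotide-wise
definition), and raw sums are exactly additive, so `coarsen` reproduces
direct scoring at any multiple of 10 kb without recomputation (tested
exactly against a per-nucleotide oracle). Normalization divides by the
mean over unmasked windows and precedes technical-replicate averaging;
replicate averaging is an element-wise mean with the union of masks. An
optional per-sample flag doubles raw X/Y scores of male samples to
compensate haploid sex chromosomes; it is off by default because domain
callers typically already account for this upstream.

## Correlation and clustering

Pearson correlations are computed over windows unmasked in both tracks
(autosomes only by default; a flag admits X/Y), with zero-variance
tracks reported as missing rather than an error. Sample clustering is
complete linkage on distance 1 − r. The similarity is *centered*
Pearson by default — the same quantity used everywhere else in the
package — with uncentered (cosine) correlation available as a switch,
since hierarchical-clustering software differs on this and published
descriptions rarely say which was used. Inputs are sorted by sample id
before linkage so tied merges are deterministic. Boundary meta-profiles
pool every domain's 5′ boundary with its mirrored 3′ boundary so that
positive offsets consistently point into the domain; bins extending past
a chromosome end are dropped from that boundary's average.

## Conserved and variable zones

For each 10 kb window the threshold σ(w) is the sample standard
deviation (n−1 denominator) of the included samples' normalized scores
at that window; *high* means score > σ(w), *low* means score ≤ σ(w),
both strict as stated. Two consequences are deliberate and tested: a
window where all samples agree at a positive value has σ = 0 and is
conserved-high, and an all-zero window is conserved-low. GREEN requires
at most 2 high calls overall and at most 1 per category
(granulocyte/CD34+/AML — all AML samples form one category here; K562
lines are excluded); RED is the mirror image on low calls; everything
else is YELLOW. With ≥ 2 samples per category the RED and GREEN
conditions cannot both hold. On chrY only male samples enter σ and the
counts. A `global` σ rule (one pooled standard deviation over all
samples and windows) is implemented as an alternative reading of
"a threshold of 1 standard deviation", since a per-window and a global
threshold are both defensible; per-window is the default as the literal
reading. Zone fractions are reported as percentages of unmasked
(non-deadzone) bp and always sum to 100.

## Differential LOCKs

LOCK bases of the first-listed category are found as maximal contiguous
runs of unmasked windows in which at least one sample of the category is
positive, kept when every sample is positive in at least 50% of the
run's windows. The any-sample rule delimits "continuous stretches"
deterministically and independently of sample order; the ≥ 50%-per-row
filter is then applied to the whole run. Bases come from the
first-listed category only, so a comparison and its reverse share window
scores (which negate exactly) but not necessarily coverage.

The per-window score is the mean over all (c1, c2) sample pairs of
−log(s_i/s_j), natural log, with zeros floored at ε = 10⁻⁶ (configurable)
inside the log — the floor preserves exact antisymmetry between the two
orientations and bounds |SLR|. On X/Y windows only same-sex pairs enter
the mean; with no same-sex pair those windows are undefined and skipped.
Within each base, maximal runs of strictly same-sign SLR become blocks
scored by their window sum; zero-SLR windows terminate runs and belong
to no block, and blocks never span bases.

Significance thresholds are linear-interpolation ("type 7") sample
quantiles of all non-chrY block scores of the comparison, one pooled
distribution for both tails: a positive block passes level p iff its
score strictly exceeds Q(p), a negative block iff it falls strictly
below Q(1−p); chrY blocks inherit the autosomal thresholds. Because of
interpolation and the strict inequality, the realized flag rate at level
p is bounded by (1−p) + 1/n rather than equal to 1−p; the null
calibration test accounts for this granularity explicitly. No
multiple-testing correction is applied — the thresholds are descriptive
ranks, not p-values.

The canonical battery runs ten ordered comparisons: CD34+ vs
granulocyte (both directions), CD34+ vs AML cluster A (both), granulocyte
vs AML A (both), CD34+ vs AML B (both), and K562 control vs
K562+G9a-inhibitor (both). The AML A/B split is taken from the sample
sheet (it reproduces an unsupervised clustering of the samples, which
`hcluster_samples` can propose, but is not re-derived inside the caller).

## Enrichment and gene sets

Fold enrichment is the ratio of feature density inside a window set to
the genome-wide density over all unmasked windows, with bp counted on
non-deadzone lengths — so the all-windows set has fold exactly 1.
Interval features contribute covered bp (overlaps merged), point
features contribute counts. Gene membership in a block set is ≥ 1 bp
overlap of the gene body, strand ignored; under the half-open convention
an exactly abutting gene does not overlap. An alternative
fully-contained rule would only shrink gene counts; overlap is the
default because block boundaries are window-quantized and systematically
clip gene bodies. Intersection of two gene sets is reported as a
percentage of the first set.

## Synthetic data

The generator emits domain-level files — the pipeline's actual input —
not reads; alignment and domain calling are upstream of this package's
scope. A LOCK skeleton shared by all samples is drawn per chromosome:
planted blocks are reserved first, then free segments are filled by
alternating exponential gaps and log-uniform LOCK lengths (defaults
50–500 kb, matching the multi-100 kb scale of real LOCKs) with the gap
mean set so LOCKs cover a target fraction of the genome (default 0.4).
Depth noise is multiplicative lognormal with one draw per (sample,
domain) — domain-level noise is what the domain-mean score model
propagates; window-level wiggle within a domain is intentionally not
modeled, so simulated tracks are blockier than real ones and tests on
them validate the score algebra and calling logic, not robustness to
within-domain variance. Defaults: base depth μ = 2 read-counts/nt,
σ = 0.25 (giving ~25% depth scatter, comparable to replicate scatter in
ChIP at domain scale), conserved-high depth μ_high = 6, differential
log-fold δ = 1, deadzone fraction 2% in 2 kb pieces. Features are placed
by a Poisson process with a k-fold intensity step inside a named planted
block.

The standard power experiment uses 3 vs 3 samples and a 500 kb planted
block with δ = 1 and σ = 0.25 on a 200 Mb single-chromosome genome. The
genome length is chosen so that the one systematic artifact of
per-sample mean normalization — the elevated category's genome mean is
inflated by its own planted block, biasing the mean SLR by roughly
−log(1 + f·(e^δ−1)) with f the block's share of LOCK bp — stays an
order of magnitude below the Monte-Carlo standard error of the
experiment (≈ 0.011 vs ≈ 0.014 at 200 seeds). At these conditions the
block is recovered as an α = 0.99 positive block in ≥ 95% of seeds
(measured: ~100%). For null calibration the planted block's length is
drawn from the background LOCK length distribution so that with δ = 0
its score is exchangeable with every other block, making the expected
discovery rate exactly the quantile's granular tail rate
(n − ⌊(n−1)p + 1⌋)/n.

The enrichment-recovery experiment compares the estimated fold against
its exact expectation k/(1 + f_b(k−1)) — slightly below k because the
genome-wide density in the denominator includes the enriched block
(f_b = block fraction, 0.01 in the default design).

## Pipeline and determinism

Stages communicate through window-matrix TSVs so each stage can be
re-run in isolation and every intermediate is a flat, inspectable file.
All randomness flows from the single config seed; outputs contain no
timestamps and floats are printed at fixed precision, so a re-run with
unchanged inputs is byte-identical (wall time and row counts go to the
log stream, and a manifest records input hashes, config and row counts).

## Limitations

* The generator does not model platform effects, GC/mappability bias
  beyond deadzones, copy-number changes, or within-domain signal decay;
  conclusions about those require real data.
* Zone classification and dLOCK calling are rank/threshold procedures
  without an error model; quantile flags rank blocks within one
  comparison and are not comparable across comparisons with different
  block-count distributions.
* Boundary meta-profiles weight every boundary equally regardless of
  domain size.
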