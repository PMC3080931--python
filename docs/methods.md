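# Methods

`mirperm` re-implements, as a reusable and testable pipeline, a classic
small-sample miRNA microarray analysis: probe-level background filtering,
probe→miRNA summarisation, permutation-based differential expression with the
signal-to-noise-ratio (SNR) statistic, score-thresholded target mapping with
Fisher-exact functional enrichment, and the replicate-assay statistics used to
confirm array findings (fold changes, Grubbs outlier screening, Welch's
t-test, 2^−ΔΔCt quantification). A synthetic-data generator reproduces the
study design — 12,033 probes interrogating 534 miRNAs on three treated and
three control arrays — with known ground truth, so every stage is tested
end to end without any external data.

## Preprocessing

A probe is *detectable* when its mean intensity across all six arrays
strictly exceeds the background threshold. The default threshold is 30
intensity units, approximately the median signal per array for data of this
type; `default_threshold` recomputes the per-array-median rule when a
data-driven value is preferred. Filtering happens at probe level, before
summarisation, so the filter report counts probe records; the number of
miRNAs retaining at least one probe defines the detectable miRNA set.
Retained probes are collapsed to one row per miRNA by the per-sample median
over that miRNA's probes — robust to a single aberrant probe, which matters
because probe affinity effects are shared across samples. No normalisation
is applied; the pipeline starts from extracted signals.

The filter rule (mean over all samples, strict inequality) is one of several
defensible readings of "expressed above background"; it is the simplest rule
that makes the threshold boundary deterministic. Summarisation by median was
chosen over the platform vendor's proprietary scheme, which is not public.

## Marker selection

For miRNA *i* with treated values A and control values B (on
log2(intensity + 1)):

    SNR_i = (μ_A − μ_B) / (σ_A + σ_B)

with sample (n−1) standard deviations, each floored at `sigma_floor`
(default 1e-8; an optional mode floors at 0.2·|μ| per group instead,
following the convention of the marker-selection tool family this statistic
comes from). The signed fold change is computed on linear-scale group means:
the ratio r = mean_treated/mean_control is reported as r when r ≥ 1 and as
−1/r otherwise, so −5.5 means 5.5-fold lower in treated samples. Log scale
for the SNR stabilises variance; linear means match the conventional FC
definition.

**Permutation null.** All sample→group relabelings preserving group sizes
are enumerated when their count C(n, k) does not exceed the requested number
of permutations (default 2,000) — a 3-vs-3 design has C(6,3) = 20, so the
null is always exhaustive there; larger designs fall back to seeded sampling
without replacement. A single miRNA's 20 relabelings limit its own empirical
p-value to ≥ 1/20, far above the 0.005 working cutoff, so p-values are
*smoothed* by pooling null statistics across miRNAs:

    p_i = (b_i + 1) / (N + 1),   b_i = #{ |null| ≥ |SNR_i| in the pool }.

**Contaminated-null exclusion.** The pool deliberately excludes, for every
miRNA, the statistics of the observed assignment and of its mirror (which is
its exact negation). Under the null hypothesis all relabelings are
exchangeable, so this exclusion does not disturb calibration — the type-I
check below confirms it. Under the alternative, however, the observed split
of a truly differential miRNA reproduces its (large) observed statistic, and
with many responding miRNAs these entries would dominate the pool's tail and
mask weaker true positives: with 89 strong spikes among 500 miRNAs, full
pooling caps recovery near the top two dozen markers. Excluding the two
signal-bearing relabelings removes that contamination while keeping the
pooled resolution of ≈ 1/(18·m). The exclusion is exposed as a flag
(`exclude_signal_splits`) for sensitivity analyses.

**Resolution floor.** With m detectable miRNAs the smallest attainable
smoothed p is 1/(18m + 1), and therefore the smallest attainable
Benjamini–Hochberg FDR when r markers are truly differential is about
1/(18r). A study with r ≈ 89 positives clears an FDR cutoff of 0.005
comfortably; designs with r ≲ 12 cannot, whatever the effect size. This is a
structural property of pooled permutation p-values in a 20-relabeling
design, not an implementation artifact, and it is why power statements in
the test suite are made at realistic spike counts.

**Calls and ranking.** BH adjustment (step-up, over detectable miRNAs only)
uses `statsmodels`; a miRNA is called differential when |FC| ≥ 1.5
(boundary inclusive), p < 0.005 and FDR < 0.005 (both strict) — the
boundaries exactly as conventionally printed. Results are ranked by |FC|
descending, then p ascending, then miRNA id, giving deterministic output.

**Reporting.** For heat-map display, selected rows are z-scored (constant
rows become zeros) and ordered by agglomerative clustering with average
linkage on 1 − Pearson correlation distance.

## Target mapping and enrichment

Predicted miRNA→gene pairs carry a 0–100 confidence score; only pairs with
score strictly greater than 70 count as targets. Overlap accounting reports
the union size, per-gene multiplicity, and the number of genes shared by at
least two miRNAs. Enrichment of a target set in a named gene set is the
one-sided Fisher exact test (hypergeometric upper tail) over the gene
universe, taken here to be all genes in the target-score table — the space
targets are drawn from. Across several miRNAs a function's "average
p-value" is the arithmetic mean of the per-miRNA p-values; a second flag
records functions below the cutoff in *every* miRNA's target set. Both
views are emitted because a mean can be dragged below the cutoff by one
extreme set.

## Assay statistics

Fold change is the ratio of condition means. Outliers in replicate series
are screened with the two-sided single-outlier Grubbs test,
G = max|x − x̄|/s against the closed-form critical value
((n−1)/√n)·√(t²/(n−2+t²)) with t the upper α/(2n) t-quantile on n−2 df
(α = 0.05 by default); one point per pass, iterated until no point exceeds
the critical value. Group comparison uses Welch's unequal-variance t-test
with Welch–Satterthwaite degrees of freedom, applied to outlier-screened
data. qPCR quantification uses 2^−ΔΔCt on mean cycle thresholds with a
caller-named reference assay — deliberately a required argument, since no
sensible universal normalizer exists — reported in the signed-FC
convention. Cross-platform agreement uses the Pearson correlation of paired
abundances (undefined, and reported as NaN, for zero-variance input).

## Synthetic data

The generator is the package's specification of "data like the study's":

- **Design defaults**: 12,033 probes / 534 miRNAs (≈ 22.5 replicate probes
  per miRNA, the emulated platform's ratio), 3 treated vs 3 control arrays,
  background level 30, detectable fraction 343/534 ≈ 0.64.
- **Intensity model**: miRNA baselines at background × 10^U(0.5, 2.0) when
  detectable, background × 10^U(−1.5, −0.3) when not — log-uniform
  abundances, the microarray convention, with a clean separation at the
  filter boundary. Probe effects are multiplicative 2^N(0, 0.25), drawn once
  per probe and shared across samples; measurement noise is multiplicative
  2^N(0, noise_sd) with noise_sd = 0.25 (log2 scale) by default.
- **Spike-ins**: selected miRNAs have the treated-group mean shifted by a
  signed linear fold change (|fc| ≥ 1); spiked miRNAs are always placed in
  the detectable class, since an undetectable spike is unrecoverable by
  construction. Ground truth records spike status and true FC.
- **Companions**: a target-score table (uniform scores on [0, 100] by
  default, 25–350 targets per miRNA), GMT gene sets with an optionally
  planted enriched set (guaranteed to contain a given target list), and
  replicate assay series with configurable mean ratio, coefficient of
  variation, and injected gross outliers at 10× the arm maximum.

One seeded NumPy `Generator` per call makes every output bit-reproducible;
the pipeline's `simulate_study` derives stage seeds from the master seed by
fixed offsets so any stage can be regenerated in isolation.

What the generator does **not** emulate: scanner artifacts, spatial or dye
biases, array normalisation, correlated miRNA co-regulation, or heavy-tailed
intensity noise. Passing tests therefore demonstrate the statistical
machinery's correctness and calibration under a faithful idealisation of the
design, not robustness to every failure mode of real arrays.

## Numerical and design choices

- Empirical p-values use add-one smoothing, so p ∈ (0, 1] always; ties are
  counted with ≥ (conservative).
- Exhaustive permutation pools are seed-independent; sampled pools draw
  distinct relabelings without replacement.
- The constant-row guard in standardisation (z = 0) and the zero-variance
  guards in SNR (σ floor), Grubbs (G = 0), Welch (p = 1 for identical
  constant groups) and Pearson (NaN) make degenerate inputs well-defined.
- Ranking ties break by id; GMT duplicate set names keep the last
  definition with a warning; genes outside the universe are dropped with a
  logged count.
- The run manifest hashes configuration (analysis parameters only, not
  filesystem paths) and every output file; the `fingerprint` field excludes
  wall-clock timestamps and is the rerun-comparison quantity.

## Problem sizes used in the test suite

Statistical checks run on scaled studies that preserve the design's ratios:
500 miRNAs × 11,250 probes for calibration (100 null replicates) and power
(89 spike-ins drawn from [−5.5, −1.5]), smaller bundles for integration
tests. These sizes keep the suite fast while leaving the per-miRNA probe
multiplicity, group sizes and noise level at their study-scale values, which
is what the calibration and power properties depend on.

## Known limitations

- The smoothed p-value estimator is a principled stand-in: the original
  marker-selection tool's exact smoothing algorithm is not publicly
  specified, so numerical agreement with historical outputs is not claimed —
  only the qualitative behaviour (sub-1/20 resolution, calibration, down-only
  calls under down-only truth).
- FDR is adjusted over detectable miRNAs only.
- The FDR resolution floor (≈ 1/(18r)) limits three-criterion discovery in
  designs with very few true positives; see Marker selection.
- Fisher enrichment treats genes as exchangeable; no gene-length or
  expression bias correction is attempted.
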