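# Methods

`uromet` implements the statistical workflow used to analyse untargeted
LC-MS urinary metabolomics data from a birth cohort: a feature-table
preprocessing cascade, PCA-based quality control, design-based class
balancing, PLS2 classification with stability selection, a
classifier-agnostic evaluation harness, permutation significance, and
univariate FDR screening. This note records the models, the defaults
and why they are what they are, the numerical conventions, and the
limits of what the synthetic-data tests demonstrate.

## Data model

A `FeatureTable` is an injections × features intensity matrix. Rows
carry a role: **Study** (a cohort sample), **QC** (a pooled aliquot of
every study sample, injected repeatedly; stable by construction), or
**Blank** (mobile-phase-only injection exposing contaminant features).
Features are Rt_mass variables (retention time + m/z, e.g.
`1.23_180.0634`). Missing intensities are explicit (`NaN`), and in
these data missingness is left-censoring-like: low-abundance signals
drop below the detection/peak-picking threshold.

## Preprocessing cascade

Applied in a fixed order; filters only ever drop feature columns,
never alter retained values, and the per-rule removal counts telescope
exactly:

1. **Missing-in-QC filter** — a feature with any missing QC value is
   unreliable and removed (study/blank missingness is not considered).
2. **Blank-ratio filter** — remove features with
   P95(Blank)/P5(QC) > 0.20. Percentiles use linear interpolation of
   order statistics; a missing blank entry counts as zero signal; a
   feature whose QC 5th percentile is not positive cannot pass.
3. **QC CV filter** — remove features with SD/mean over QCs > 20%.
   The sample (n−1) SD is used: QC counts are small.
4. **Imputation** — each missing value is replaced by a uniform draw
   on (0, minimum observed value of that feature). Given left-censored
   missingness this is the least-assumption fill; it is seeded and
   reproducible.
5. **PQN** — probabilistic quotient normalization. Each sample is
   divided by the median over features of its quotients to a reference
   spectrum; the reference is the feature-wise **median of the QC
   samples** (the pooled, stable injections; a study-median fallback
   is available). The quotients are returned for audit — on synthetic
   data they track the true dilution factors with r > 0.99, and
   re-normalizing a dilution-only perturbation of an already
   normalized table restores it to well under 1% relative error.
6. **QC CV re-filter** — the 20% CV rule applied again on normalized
   intensities.
7. **log + center** — natural log, then column mean-centering, for
   multivariate modelling. (Fold changes in the univariate module use
   log2 regardless, matching volcano-plot convention.) The natural-log
   choice for model input is a convention, isolated behind the API.

One consequence of the mean-pooled QC reference worth knowing: on
log-normal data the pooled mean exceeds a typical sample's level, so
PQN quotients sit at a constant slightly below 1 even with no dilution
at all. The common factor cancels in every downstream statistic; only
the *between-sample variation* of the quotients matters.

## PCA quality control

PCA is fitted by SVD of the centered matrix; loading signs are fixed
(largest-magnitude element positive) so output is deterministic. The
component count is the smallest number reaching 60% cumulative
explained variance. Each sample is then scored by

- **Hotelling T²** = Σₐ t²ₐ/λₐ, against the training-set limit
  (n−1)A/(n−A) · F(1−α; A, n−A), and
- **Q** (squared residual distance to the model plane), against the
  Jackson–Mudholkar limit computed from the residual eigenvalue
  spectrum (θ₁, θ₂, θ₃).

These are the standard chemometric limit formulas. Under data
simulated from the PCA model itself (n = 2000) both flag rates land in
[0.03, 0.07] at α = 0.05. The pipeline excludes samples flagged by
either test at α = 0.05 and reports them.

## Onion D-optimal class balancing

With strongly unbalanced classes (e.g. 170 vs 35), a representative
subset of the majority class is selected in the joint geometry of the
PCA scores plus the Q coordinate, each standardized to unit variance
(Q is a squared distance and would otherwise dominate). Candidates are
ranked by Euclidean distance from the centroid and split into
**3 concentric layers** (the count is configurable; equal-count
quantile shells, sizes within one of each other). The subset size k is
apportioned across layers by largest-remainder rounding (each layer
contributes when k allows), and within each layer a D-optimal subset
is found by **Fedorov exchange** on the design matrix [1 | coords]:
best-improving single swaps from a random non-singular start, 20
random restarts, best local optimum kept. On 10-choose-4 instances the
exchange reaches the exhaustive optimum. Default k is
⌈1.2 × minority size⌉, slightly above the minority class, mirroring
how such balancing is used in practice; k is caller-overridable.

## PLS2 classification and stability selection

PLS2C regresses a dummy-coded (one-hot) class response on X by NIPALS
with X- and Y-deflation. Scores are mutually orthogonal; with
`n_components` equal to the rank of X the fitted values coincide with
least squares (tested to 1e-6), and a single-column response reduces
to PLS1. Class prediction takes the larger dummy prediction, ties to
the lower label index.

**VIP** per feature j is
√(p · Σₐ SSₐ w²ⱼₐ / Σₐ SSₐ), with SSₐ the response variance captured
by component a; Σⱼ VIP²ⱼ = p by construction, so VIP ≥ 1 is the
conventional "above average relevance" cut.

**Component count** is chosen at the first maximum of cross-validated
MCC: the smallest A with MCCcv(A) ≥ MCCcv(A+1) (ties resolve to the
smaller model), else the cap.

**Stability selection** builds 200 sub-models (50 at desk scale in the
acceptance runs). Each sub-model:

1. draws a class-stratified 80% subsample without replacement (a
   bootstrap alternative is exposed through the subsample fraction);
   the remaining 20% is out-of-bag;
2. iteratively fits PLS2C on the subsample, scores the current feature
   set by cross-validated MCC, removes features with VIP < 1, and
   repeats (cap 10 rounds); the feature set with the best MCCcv wins
   (ties to the earlier, larger set);
3. refits on the winning set and predicts the out-of-bag samples.

Aggregation: per-feature **selection frequency** over sub-models, and
per-sample out-of-bag class by **majority vote** (ties to the lower
class index), summarized as **MCCoob**. Features at frequency ≥ 0.5
are reported as "relevant", always alongside the full frequency table
so the threshold hides nothing.

Inside sub-models the MCCcv uses a single 5-fold stratified pass; the
outer, reported MCCcv uses the repeated scheme (50 × 5-fold by
default). Using the full repeated scheme inside every elimination
round of every sub-model would multiply cost by ~50 while changing
only which of two near-tied feature sets wins occasionally; the
package treats the inner scheme as configurable with the single-pass
default.

**MCC** is (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)), defined 0
when a margin is empty. **MCCcv** pools out-of-fold predictions within
a repeat, computes one MCC per repeat, and averages across repeats —
pooling first stabilizes fold-level MCC at the small class sizes
(down to 11 vs 13) this design targets. Folds are stratified
throughout; unstratified 5-fold splits of an 11-member class
frequently leave folds without the class entirely.

**Permutation test**: the class labels are permuted (X untouched),
the scalar performance statistic recomputed, and
p = (1 + #{permuted ≥ observed})/(n_perm + 1). Under a null statistic
the p-values are uniform (KS distance < 0.1 over 200 replicates at
n_perm = 99).

The harness is classifier-agnostic: anything with `fit`/`predict`
(the random-forest plug-in uses scikit-learn's implementation with
the conventional 500 trees and √p features per split; tree internals
are deliberately not reimplemented) is evaluated through the same
code paths as PLS2C.

## Univariate screening

Per feature: fold change = ratio of group **medians** on normalized,
un-logged intensities (medians pair naturally with the rank test;
means are available by configuration), reported as log2FC;
Mann-Whitney two-sided p (exact enumeration when n₁+n₂ ≤ 20 without
ties, tie-corrected continuity-corrected normal approximation
otherwise — the approximation agrees with the exact p to ~0.006 on
average at 8+8, with a known worst case of ~0.011); and Storey
q-values. π₀ is estimated from the λ-grid 0.05…0.95 by a least-squares
cubic evaluated at the largest λ, clipped to (0, 1] (an interpolating
spline evaluated at the grid end would return the raw λ = 0.95
estimate unsmoothed, defeating the purpose; a fixed-π₀ override
provides the bootstrap-style alternative). With π₀ = 1 the q-values
reduce exactly to Benjamini–Hochberg. The volcano table flags
|log2FC| ≥ 1 and p ≤ 0.05.

## Metadata screening

2×2 factors: Fisher's exact test, two-sided by the point-probability
rule (sum of hypergeometric probabilities of tables no more likely
than the observed; the convention of R's `fisher.test`), which
reproduces the published cohort-table p-values at three decimals and
matches exhaustive integer-arithmetic enumeration over every table
with total ≤ 30. Continuous factors: Shapiro-Wilk on each group;
both p > 0.10 → t-test (Welch by default, pooled by flag), otherwise
Mann-Whitney. The dispatch is a pure function of the two gate
p-values.

## Synthetic cohorts

The generator produces the structure the analysis assumes, with known
ground truth:

- **Study intensities**: log-normal, per-feature location uniform on
  log [10⁴, 10⁶] and log-SD uniform on [0.2, 0.8] — a wide
  concentration range with feature-specific variability, as urine
  presents.
- **Planted signal**: `n_discriminant` features (default 10 of 500)
  shifted in class "case" by `effect_size` (default 2) within-group
  SDs on the log scale.
- **Dilution**: per-sample multiplicative factor uniform on
  [0.5, 2] — urine concentration varies severalfold between newborns.
- **QCs** (default 10): per-feature mean of the undiluted study
  samples times log-normal noise calibrated so the realized CV matches
  the target (default 0.10), mirroring a pooled aliquot.
- **Blanks** (default 5): 2% of the median study intensity as
  background, with 10 features contaminated at 50% of median — true
  positives for the blank-ratio filter.
- **Missingness**: values in the lowest intensity decile of their
  feature go missing with probability 0.3 — left-censoring-like,
  which is exactly the regime the below-minimum imputation rule
  assumes.
- One global seed fans out to independent per-stage child streams, so
  e.g. the missingness pattern can be switched off without changing
  the intensities (used by the tests).

Default sample size is 30 per class: comparable to the minority-class
scale of the motivating cohort while large enough for stability
selection to be well-posed.

What the generator does **not** emulate: chromatogram/spectrum-level
structure, retention-time drift, batch effects, correlated feature
blocks (co-eluting adducts/fragments of one metabolite), or
heavy-tailed contamination. Passing tests therefore demonstrate that
the pipeline recovers the structure it assumes — planted effects,
multiplicative dilution, left-censored missingness — not that it is
robust to every artefact of real LC-MS data.

## Numerical conventions and degenerate inputs

- Percentiles: linear interpolation of order statistics; CV: sample
  (n−1) SD.
- PCA loading signs: largest-magnitude element positive. NIPALS
  convergence: relative score change < 1e-12, cap 500 iterations;
  requesting components beyond the usable rank raises.
- MCC is 0 on an empty margin; majority-vote ties go to the lower
  class index; dummy-prediction ties go to the lower label index;
  first-maximum ties go to the smaller component count.
- Samples never out-of-bag are excluded from MCCoob with a warning.
- Features entirely missing, tables without QC/Blank rows, classes
  smaller than the fold count, and all-zero contingency tables raise
  `ValueError` with the violated precondition named.

## Known limitations

- MCCoob from majority-vote out-of-bag aggregation is unbiased near 0
  under the null but has standard deviation ≈ 0.2 at n = 60 (votes
  are strongly correlated across sub-models, so it behaves like a
  single classifier's MCC); single-run MCCoob values of ±0.25 on null
  data are not unusual and the permutation p, not MCCoob alone,
  should carry the significance claim.
- Storey's π₀ smoother is a least-squares cubic, not a smoothing
  spline; on very small feature sets (m < ~100) the fixed-π₀ = 1
  (Benjamini–Hochberg) mode is safer.
- The Fedorov exchange is a local search; 20 restarts are empirically
  sufficient at cohort sizes (≤ ~200 candidates) but optimality is not
  guaranteed in general.
- The pipeline analyses one ionization mode per invocation; positive-
  and negative-mode tables are two independent runs, never merged.
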