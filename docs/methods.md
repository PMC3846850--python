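# Methods

## Problem setting

`mrmrsvm` builds parsimonious linear classifiers of a binary clinical
phenotype (the motivating case: estrogen-receptor status of breast tumors)
from genome-wide expression data, where tens of thousands of probes dwarf the
few hundred available samples.  The package has four scientific layers: a
microarray normalization chain, a nonparametric mutual-information relevance
measure with mRMR redundancy-aware ranking, a feature-selecting linear SVM
whose model size is chosen by a nested-CV one-standard-deviation rule, and a
fixed, published three-gene ER-status rule that can be transferred across
array platforms.  A synthetic cohort generator with planted signal makes the
whole pipeline testable without any external data.

## Normalization chain

Raw one-color intensities `g_ij` (feature j, sample i) pass through four
steps:

1. **Floor** — every value below 0.1 is set to 0.1.  Removes nonpositive and
   near-zero intensities so later ratios and logs are defined.
2. **Per-array median scaling** — each array (sample column) is divided by
   its own 50th percentile.  Median = linear interpolation at even counts
   (percentile dialects differ; this one is stated because it matters for
   exact post-conditions).  Post-condition: every column median is 1.
3. **Per-feature median centering** — each feature row is divided by its
   median across samples; row medians become 1.
4. **z-score** — per feature, subtract the mean μ_j and divide by the
   standard deviation σ_j.  We use the *population* convention (divisor n),
   recorded in `NormalizationParams.sd_convention`; the choice only has to be
   internally consistent, since every consumer works on the same convention.

z-scores are always refit on the cohort being classified, never copied from
a training cohort.  The reason is the transfer property the whole
cross-platform argument rests on: `z(a·x + b) = z(x)` for any per-feature
gain `a > 0` and offset `b`, so platform-specific affine distortions cancel
exactly.  External cohorts deposited on log scale are exponentiated first
(`exponentiate`, base configurable, natural by default) so their dynamic
range matches intensity-scale cohorts.

A single-sample alternative (`log_actb_normalize`) replaces steps 2–4 with
`log g − log g_ACTB` against the beta-actin housekeeping probe: it needs no
cohort statistics at all, at the cost of relying on housekeeping stability.

Missing cells are imputed with the per-feature median over present samples
(after presence filtering, before normalization); the imputation count is
logged.  The presence filter keeps features observed in at least
`ceil(0.25·n)` samples (overridable) and, optionally, only those carrying a
database annotation.

## Mutual information and mRMR

Relevance of a continuous feature G to the class C is

    I(G;C) = Σ_c P(c) ∫ p(g|c) · log₂ [ p(g|c) / p(g) ] dg

with `p(g|c)` estimated by a Parzen window: a sum of Gaussian kernels at the
observed class-conditional values, bandwidth per class by the Silverman
rule-of-thumb `0.9·min(sd, IQR/1.34)·n^(−1/5)` (falling back to the overall
spread when a class is internally constant).  The integral is a fixed
512-point grid over the data range ± 3 bandwidths; halving the grid moves
estimates by well under 1e-3 bits on reasonable data, which the tests check.
Densities are renormalized to probability masses on the grid before taking
the divergence, which makes the estimate a discrete KL and hence
nonnegative by construction.  MI is reported in **bits**: for a binary
phenotype the class entropy (≤ 1 bit) gives the natural ceiling, and
relevance values are directly comparable to it.

Numerically, the 1-D densities are evaluated by linear binning plus an FFT
Gaussian convolution on the same grid (the padded FFT length keeps kernel
tails from wrapping); a direct kernel-sum evaluator is retained internally
and the two agree to ~1e-6 in probability mass, far below the estimator's
statistical error.  Feature–feature MI (the redundancy term) uses a product
Gaussian kernel on a 64×64 lattice with the same mass-renormalization
construction, computed in the log domain because the product of two tiny
marginals can underflow where the joint mass is still positive.

mRMR ranking is greedy with the mutual-information-difference criterion:
rank 1 maximizes I(f;C); rank t+1 maximizes
`I(f;C) − (1/t)·Σ_{s selected} I(f;s)`.  Ties break on input feature order,
so rankings are deterministic.  Exact greedy is quadratic in feature count,
so by default the learner evaluates redundancy only among the
top-`pool_size` (100) features by relevance — a standard mRMR practice; the
oracle-equivalence tests run with the pool disabled so the criterion itself
is pinned exactly.  The quotient (MIQ) criterion is deliberately not
implemented.

Ranking stability between cohorts is quantified with the Jaccard overlap
|A∩B| / |A∪B| of top-k lists (0/0 defined as 1).

## Feature-selecting SVM and the one-SD rule

The classifier is a soft-margin linear SVM (`sign(w·x + w0)`, ties to the
positive class), C = 1 — the default of the reference SMO implementation —
backed by scikit-learn's SVC.  Model size is selected by nested
cross-validation:

1. Split the cohort into k = 10 stratified folds (within-class shuffle by a
   seeded generator, dealt round-robin with a running pointer: fold sizes
   and per-class counts each differ by at most one; a class smaller than k
   is allowed and simply absent from some folds).
2. For each fold i, rank features by mRMR **on the training portion only**,
   then record held-out accuracy with the top r = 1..r_max features
   (r_max = 18 by default).
3. Aggregate to the accuracy curve (a_r, σ_r), σ_r the sample SD (divisor
   k−1) over the k fold accuracies.
4. r* = smallest r with `a_r + σ_r ≥ max_r' a_r'` — the most parsimonious
   model statistically indistinguishable from the high-water mark.  r*
   never exceeds the argmax and equals it when all σ are 0 and the max is
   unique.
5. Re-rank on the full cohort and train the final model on the top r*
   features; the reported CV accuracy is (a_{r*}, σ_{r*}).

Per-fold ranking deliberately sees nothing of the held-out fold; a test
corrupts a held-out fold and asserts that fold's ranking is unchanged.  The
whole fit is deterministic given the seed.

## The fixed three-gene ER rule

The published rule scores a tumor as
`−0.2466·z(AW972815) + 2.2165·z(GATA3) + 1.2934·z(CA12)`, ER+ iff the score
is nonnegative, with z-scores fit on the cohort being classified.  The three
coefficients are exact published values; the published intercept is not
recoverable, so the threshold defaults to 0 on z-scored inputs, is exposed
as an option, and `refit_threshold` can re-derive an accuracy-maximizing
intercept from any labeled cohort (candidate cutoffs are score midpoints;
ties keep the smallest cutoff, so the refit is deterministic).  For
Affymetrix cohorts a packaged one-to-one probe map (230356_at, 209602_s_at,
203963_at → the Agilent ids) renames probes before scoring; only the three
probes used are z-scored.

## Synthetic cohorts

The generator emulates a one-color expression cohort: log2-scale signals
exponentiated to raw intensities (log2 is the field's log-intensity
convention), per-feature baselines ~ Normal(3, 0.5) on log2 scale,
within-class SD 1.  Defaults mirror the study conditions the rest of the
package was designed around: n = 200 samples, positive prior 112/176,
3 informative probes with a 2-SD between-class shift, 2 redundant probes per
informative one (parent signal + Normal(0, 0.3) — chosen so duplicates track
parents as tightly as duplicate probes of the same gene do on real arrays),
989 class-independent noise probes, one low-variance housekeeping probe, and
98% presence (missing cells drawn per cell).  The planted truth is returned
with the cohort so recovery can be scored.  Platform pairs share the latent
signal; platform B applies per-feature gain ~ LogNormal(0, 0.3), offset ~
Normal(0, 0.5) and independent measurement noise (SD 0.1 on log2 scale), and
renames every probe; rare negative intensities after the offset are clipped
to 1e-3.

What the generator does **not** emulate: probe-sequence effects, spatial
array artifacts, batch structure, correlated noise across probes beyond the
planted redundancy groups, heavy-tailed outliers, or survival outcomes.
Passing tests therefore demonstrate internal correctness and calibrated
behaviour under idealized log-normal cohorts, not clinical performance.

## Numerical and degenerate-input choices

- Constant features are rejected by z-scoring and by MI (zero variance has
  no defined density); callers filter them first.
- Small negative MI estimates are clipped to zero (the mass-renormalized
  construction already guarantees nonnegativity; the clip is a guard).
- Decision ties (`w·x + w0 = 0`) go to the positive class, documented and
  tested.
- All randomness flows through `numpy.random.default_rng(seed)`; identical
  seed and inputs give bit-identical cohorts, folds and fitted models.

## Problem sizes used in the checks

The reproduction script (`scripts/acceptance.py`) measures MI calibration at
n = 400–2,000, greedy-vs-brute-force agreement on ten 10-feature fixtures,
planted recovery over 10 seeds of the default cohort (the test suite runs
20), three null cohorts, and five platform pairs of 150 samples — sizes
chosen to exercise every component at the conditions above while keeping a
full run in the minutes range.

## Known limitations

- Fixed-bandwidth Parzen MI underestimates strong dependencies (a thin
  joint-density ridge is smeared by the kernel); rankings are insensitive to
  this compression but absolute redundancy values saturate well below the
  true MI for near-duplicate features.
- With k = 10 folds of ~20 samples, per-fold accuracy SD is binomial-scale
  (~0.05–0.07), so the one-SD rule selects aggressively small models
  (typically r* = 2 at the default planted-signal strength); this is the
  rule working as defined, not an estimation failure, but it trades a few
  accuracy points for parsimony at these cohort sizes.
- The three-gene rule's intercept is a design default (0 on z-scores), not a
  published value; cohorts with class priors far from the training prior may
  benefit from `refit_threshold`.
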