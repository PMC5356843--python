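# Methods

## Model overview

The package treats prognostic classification in a two-class cohort
(good vs. poor prognosis) as a routing problem. Two base biomarkers are
available:

- **Expression arm.** Feature selection keeps the `k = 1000` genes with the
  largest absolute difference of class means on the log-intensity scale
  ("fold change" for log-transformed microarray data), then a diagonal
  linear discriminant analysis (DLDA) is fit: per-class per-gene means, a
  pooled within-class variance per gene (within-class sums of squares over
  n − 2), and empirical class priors. The discriminant is
  `D_c(x) = Σ_g (x_g − μ_{g,c})²/σ²_g − 2 ln π_c`; the score reported is
  `D_first − D_second`, negative favouring the first listed class. A score
  of exactly zero is a tie and resolves to the first listed class, with the
  zero score itself serving as the audit flag.
- **Clinical arm.** Binomial logistic regression over the clinico-pathologic
  variables with stepwise variable selection under AIC (2p − 2 log L).
  `both` (default), `forward` and `backward` directions are supported;
  categorical variables enter and leave as whole indicator blocks, one
  parameter counted per indicator.

The *classifiability* step regresses the per-patient LOOCV error indicator
of the expression arm on each clinical variable separately (univariate
logistic fits) and selects the smallest-AIC variable. Patients whose
predicted error probability is below 0.5 are "easy to classify" with
expression data; the rest are "hard". The multi-step classifier retrains
the expression arm inside the easy group (gene selection redone there, so
nothing about the hard group leaks into it) and the clinical arm inside the
hard group, then routes test patients by the classifiability model.

## Key parameters

| parameter | default | meaning |
| --- | --- | --- |
| `k` | 1000 | genes kept by fold-change ranking (fixed, avoiding a third CV level) |
| routing threshold | 0.5 | predicted error probability at or above which a patient is "hard" |
| `max_missing` | 5 | clinical variables missing in more than this many patients are dropped, then incomplete patients removed |
| minimum trainable group | 3 per class | an easy/hard group smaller than this falls back to training that arm on the full training cohort, flagged |
| `n_repeats` | 200 | leave-two-out CV repeats (one held-out patient per class each) |
| bootstrap resamples | 1000 | percentile bootstrap over held-out pairs for 95% intervals |
| RF trees | 500 | random-forest integration baseline, `sqrt(p)` features per split, seeded |

## Numerical choices

- **Logistic fitting.** All logistic fits go through an in-package
  Newton/IRLS solver with step halving (the stepwise search inside the
  leave-two-out harness performs ~1e5 fits per study, so per-fit overhead
  matters). Two saturated cases — intercept-only and intercept plus one
  two-valued covariate — use their closed-form maximum-likelihood estimates.
  Divergence (non-convergence, or any |coefficient| above 30, the scale at
  which fitted probabilities are numerically 0/1) marks the fit as
  separated; it is then refit with a 1e-8 ridge on the slopes (never the
  intercept) under a 30-iteration cap, keeping estimates finite and
  deterministic, and the flag is retained on the model. AIC always uses the
  unpenalized binomial log-likelihood at the returned coefficients. The
  solver is cross-checked against statsmodels in the test suite.
- **Variance floor.** Pooled per-gene variances are floored at 1e-8 times
  the median positive pooled variance (1 if none), so degenerate genes
  cannot produce infinite discriminant terms.
- **Leave-one-out scores.** The pre-validated decision vector (and hence
  the LOOCV error vector, which is its thresholding — the two agree exactly
  by construction) is computed with per-fold class sums formed as masked
  matrix products with a literal zero weight on the held-out sample. This
  makes each patient's score bitwise independent of that patient's own
  label, which the leakage tests assert by mutation. Inside this fast path
  the top-`k` genes are found by unordered partition rather than a full
  sort: only set membership enters the discriminant sum, and ties at the
  boundary have measure zero for continuous expression values. The public
  `select_top_genes` uses a stable full sort with input order breaking ties.
- **Ties and thresholds.** Logistic probability exactly at the threshold
  assigns the positive class; DLDA ties assign the first listed class.
- **Seeding.** Every stochastic entry point takes an integer seed;
  replicate seeds derive from `numpy.random.SeedSequence` and stay below
  2^31. Fits are bit-reproducible under a fixed seed.

## Evaluation design

Leave-two-out CV draws one held-out patient per prognosis class per repeat
(seeded, 200 repeats by default; exhaustive enumeration of all class pairs
is available). Because each repeat holds out exactly one patient per class,
the pooled balanced error over all held-out predictions equals the mean of
the per-repeat pair errors. The 95% interval is a percentile bootstrap over
repeats; methods compared in one call share the identical fold sequence,
and fold-level components used by several methods (the full-train DLDA, the
pre-validated vector) are computed once per fold, which cannot change any
method's output — only its cost. Within-stratum evaluation reruns the whole
harness independently inside each level of a clinical variable; levels with
fewer than 3 patients in either class are reported as not evaluable.

## What the generator emulates — and what it does not

`simulate_cohort` draws a 45-patient cohort (22 good / 23 poor prognosis by
default) with 2000 genes and 8 clinical variables. A binary stratum
variable `z` (prevalence 0.5) controls where the signal lives: inside
`z = 0`, 200 informative genes carry a ±0.5-effect shift per class
(1 standard deviation of separation, random per-gene direction); inside
`z = 1`, two binary clinical variables associate with outcome at 2.0
log-odds; the remaining clinical variables are fair-coin binary and
standard-Gaussian continuous noise. These sizes mirror a moderate bulk
expression cohort in which a prognostic signature is real but subgroup
restricted, and they make every pipeline stage testable without external
downloads.

The generator does **not** emulate microarray platform artifacts, batch or
center effects, gene-gene correlation, survival times, or clinical
variables correlated with each other; passing tests therefore demonstrate
the pipeline's statistical behaviour under clean stratum-specific signal,
not robustness to real-data messiness.

A structural property of these conditions worth knowing: patients in the
stratum without expression signal are classified at chance by the
expression arm, so their LOOCV error rate sits near the 0.5 routing
threshold (slightly above it on average, via the well-known pessimism of
leave-one-out validation of centroid classifiers on selected features). In
a minority of finite cohorts the observed rate falls below 0.5, the
classifiability model then routes every patient "easy", and the multi-step
classifier degenerates — by its own fallback rule — to the plain expression
classifier. Monte-Carlo summaries of multi-step superiority report the
strict inequality and therefore count such replicates as non-wins.

## Harness problem sizes

Monte-Carlo summaries in the test suite and acceptance script use 100
replicates for classifiability recovery, 50-100 replicates at 50 CV repeats
for the superiority and crossing comparisons, and 50 null replicates (200
CV repeats each, methods cycled, forest arm at 25 trees — null calibration
does not depend on tree count) for calibration. These sizes hold the
end-to-end study to a few CPU-minutes while keeping the binomial standard
error of each reported fraction below ~5 percentage points.

## Known limitations

- The classifiability model is univariate by design; interactions between
  clinical variables in explaining biomarker performance are out of scope.
- Routing is binary (easy/hard); no probabilistic blending of arms.
- The bootstrap interval reflects CV-repeat noise conditional on the
  cohort, not cohort-level sampling variability; on small cohorts the
  interval can exclude the population value even when the procedure is
  unbiased across cohorts.
- Stepwise selection under separation relies on the capped ridge refit;
  coefficient magnitudes in separated fits are regularization artifacts and
  should not be interpreted.
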