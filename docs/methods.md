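# Methods

## The weighted change score

Patient-reported outcome trials conventionally declare success when a
change score crosses a fixed minimal clinically important difference.
For vasomotor-symptom severity this is unsatisfying: the same raw change
is perceived differently depending on baseline severity and on whether
symptoms improved or worsened. The weighted change score makes that
dependence explicit. With `X1`, `X2` the baseline and follow-up Hot Flush
Rating Scale composites (mean of three 0–10 domains; the composite exists
only when all three domains were answered — no partial-mean imputation)
and `C = X2 − X1`:

```
C′ = w(X1) · C,   w(X1) = 1 / (1 + exp(−(b0 + b1·X1)))
```

The logistic weight is bounded in (0, 1), so weighting never flips the
direction of change and never inflates its magnitude; with slope `b1 > 0`
it grows with baseline severity. Parameters are fitted separately in the
improvement (`C < 0`) and non-improvement (`C ≥ 0`) strata — zero change
is non-improvement by definition — because deterioration and improvement
are perceived asymmetrically.

### Anchor calibration

The calibration anchor is a five-level Likert item on perceived treatment
effectiveness, coded strongly-disagree = 1 … strongly-agree = 5 with
*not applicable* collapsed to neutral (3). For each stratum the fitter
maximizes the Spearman correlation (mid-rank tie handling, the standard
convention) between `C′` and the anchor over a bounded box, by default
`b0 ∈ [−10, 0]`, `b1 ∈ [0, 5]`. Two conventions are configurable:
maximizing the absolute correlation (default, `abs_max`) or the signed
value (`signed_max`); the report always carries the signed correlations
for both raw and weighted change. Only couplets with both a complete HFRS
pair and an anchor response enter the fit; the fitted weights are then
applied to every complete couplet.

Two numerical notes. First, with `b1 = 0` the weight is constant, so `C′`
is a positive multiple of `C` and the Spearman objective equals the raw
objective exactly — the raw change score is inside the search space, and
a fitted objective can only fall below it by optimizer tolerance. Second,
the logistic saturates in floating point for |b0 + b1·X1| ≳ 37; saturated
weights are nudged to the nearest representable point inside (0, 1) to
preserve the strict-inequality contracts.

## Bayesian optimization

Both the weight fit and the tree hyperparameter search use a GP-UCB
maximizer: per independent repeat, `n_init_points` uniform-random
evaluations, then `n_iterations` evaluations at the maximizer of
mean + κ·sd of a Gaussian-process posterior (Matérn 5/2 kernel on inputs
normalized to the unit box, observation jitter 1e-6), with the acquisition
optimized over 1000 random candidate points. Defaults: 20 initial points,
10 repeats, κ = 2.576, 25 guided iterations per repeat. Repeats are
independent restarts with seeds spawned from one root seed; the best
*evaluated* point over all repeats is returned, never an un-evaluated GP
argmax. Integer dimensions are relaxed to the continuous box and rounded
at evaluation time. Given a seed, the evaluation trace is bit-for-bit
reproducible, and a larger iteration budget extends the trace as a
superset (so the best value is monotone in budget).

## Regression tree

The tree engine is written for clinical use in the rpart idiom:

- **Splitting.** Recursive binary partitioning maximizing the reduction in
  within-node sum of squares. Continuous predictors are searched over
  midpoints of sorted unique observed values; categorical predictors over
  all 2^(k−1) − 1 binary level partitions (the arm variable has k = 5, so
  exhaustive search is cheap and exact). Split quality is evaluated on the
  rows where the split variable is observed. Ties break toward the
  earliest column, then the lowest threshold / earliest partition in
  enumeration order, making fits deterministic.
- **Pruning.** A split is kept only if its sum-of-squares reduction is at
  least `cp` × root deviance. With this pre-pruning rule the tree at a
  higher `cp` is always a subtree of the tree at a lower `cp`, so the leaf
  count is monotone in `cp`.
- **Missing data.** Rows missing the primary split variable are routed by
  surrogate splits: for every other predictor, the rule (possibly
  direction-flipped) best agreeing with the primary split among rows where
  both are observed, kept only if it beats the majority-direction rule and
  ranked by agreement. Rows no surrogate can route follow the majority.
  With no missing values, predictions are identical with surrogates on or
  off.
- **Stopping.** A node splits only if it has `min_parent` rows, both
  children would have `min_terminal` rows, depth (root = 1) stays within
  `max_depth`, and the `cp` rule is met. Constant response or too few rows
  yields a single-node tree, not an error.
- **Reporting.** Prediction uses the leaf mean (the MSE-consistent choice);
  displays report the leaf median with a 95% bootstrap percentile interval
  of the median (2000 seeded resamples; a singleton leaf reports the
  degenerate interval). Which interval the original tree displays was not
  derivable from its description, so the bootstrap choice is documented
  here and seeded for reproducibility.

Collinearity screening is available as `vif_check`: each dummy-encoded
predictor is regressed on the others on complete cases, and
VIF = 1/(1 − R²) reported, with perfect collinearity surfaced as `inf`
(an advisory threshold of 5 is conventional; nothing is dropped
automatically).

Predictor coding for the VMS analysis: intervention (5 arms, never
missing), age in three bands (<50, 50–59, ≥60 years), menopausal status
(pre/peri vs post), endocrine-therapy duration dichotomized at 12 months
(symptoms are typically worst in the first year on therapy), time between
questionnaires dichotomized at 56 days (the six-week follow-up window plus
the two-week reminder period), and adherence in days left continuous. The
age cut points are the package's own choice of clinically conventional
decade-style bands; all cut points are module constants.

## Nested cross-validation

Ten outer folds (simple random shuffled assignment, seeded; no
stratification) estimate generalization MSE. Within each outer training
set, the hyperparameter box — `min_parent` 5–20, `min_terminal` 2–10,
`cp` 0.001–0.1, `max_depth` 3–7 — is searched by the GP-UCB optimizer
with inner five-fold CV MSE (negated) as the objective; the box treats the
two node-size parameters as independent dimensions, and a sampled point
with `min_terminal > min_parent` clamps the terminal size to the parent
size at evaluation. The winning hyperparameters are refit on the outer
training set and scored once on the held-out fold. The summary is the
outer-fold mean MSE with the normal-approximation interval
mean ± 1.96·sd/√k. The final reported model refits all data with the
modal fold-level hyperparameters (ties broken toward the lowest `cp`,
i.e. the least pruned); the choice of a modal refit is the package's own
convention and is stated in the report.

## Synthetic cohorts

The generator emulates the cohort structure the analysis assumes, not any
individual patients:

- latent baseline severity `10·Beta(2, 2)` (median 5.0, quartiles ≈3.3 /
  6.7), emitted as three domain scores with N(0, 0.7) noise clipped to
  [0, 10];
- intervention mix 0.27 / 0.25 / 0.11 / 0.08 / 0.29 for lifestyle / CAM /
  drug / endocrine-modification / control, with arm-specific mean raw
  changes (−1.0, −1.6, −1.2, −1.0, −0.2; CAM largest) plus N(0, 1.5)
  noise; follow-up domains add the same change to each baseline domain
  plus noise, re-clipped;
- the anchor latent is −C′ (computed with the *true* stratum weight
  curves, defaults (−10, 2.68) and (−9.45, 1.27)) plus N(0, 0.8),
  thresholded at (−2, −0.5, 0.5, 2) into the five Likert levels — so
  parameter recovery is a testable property;
- covariates drawn from two-piece (split) normal distributions
  parameterized directly by their target quartiles (age 46.3/52/61,
  VMS/week 17/38/61, days between questionnaires 45/54.5/63; durations on
  the log scale, 4.0/9.9/20.9 months), so configured medians and IQRs are
  matched by construction; adherence is days-between minus an exponential
  start lag (mean 4.5 days), matching its 41/50/60 target quartiles;
- 27% loss to follow-up (follow-up domains blanked) and 27% anchor
  missingness, applied independently; 18% missing endocrine-therapy
  duration and 5% sporadic covariate missingness.

What the generator does **not** emulate: within-patient correlation for
repeat participants (each couplet is independent), informative
missingness, digit-preference or response-style artifacts in Likert use,
and any real association between covariates and symptom change other than
the intervention effect. Tests passing on synthetic cohorts therefore
demonstrate the machinery's correctness and calibration under the assumed
structure, not clinical conclusions about real patients.

A second generator emits predictor tables with known piecewise-constant
response regions plus Gaussian noise, giving nested-CV error-floor
oracles (noiseless → MSE near 0; no signal → MSE near var(y)).

## Problem sizes and budgets

Unit and acceptance tests run the optimizer with reduced budgets (about
6–12 initial points, 4–10 guided iterations, 1–2 repeats) and cohorts of
100–400 couplets; the calibration check uses n = 5000. These sizes were
chosen so the full suite completes in about a minute while every
statistical property is still comfortably resolved; the package defaults
remain the full 20-point / 10-repeat budget.

## Known limitations

- The sign convention relating raw-change correlations to the anchor in a
  stratified analysis is ambiguous in general; both `abs_max` and
  `signed_max` objectives are exposed, defaulting to `abs_max`.
- Surrogate quality is not propagated into variable-importance measures
  (none are computed).
- The nested-CV interval is a normal approximation over 10 fold MSEs and
  is rough at that sample size.
- The logistic is the only weight family implemented; the fitting code is
  factored so another monotone family could be substituted.
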