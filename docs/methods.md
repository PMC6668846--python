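# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical decisions a maintainer should know about.  No
empirical claim here goes beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Spontaneous-report model and counting

A spontaneous report is a triple of sets: drugs, indication PTs, reaction
PTs.  Identifiers are trimmed and lower-cased at load; no synonym
resolution or de-duplication is attempted (curation of raw regulatory dumps
is out of scope — the loaders expect an already standardized table).

For a drug pair and a reaction PT the 2×2 table is: A = reports with both
drugs and the PT; B = PT without the pair; C = the pair with at least one
other reaction PT but not this one; D = the rest.  Because every retained
report has a nonempty reaction set, C equals "pair present, PT absent" and
A+B+C+D = N exactly.  Reports are treated as independent; indications
count as context (propensity features), never as events.

Degenerate conventions: PRR is 0 when A = 0, +∞ when B = 0 < A, and an
error when A + C = 0 (the pair occurs in no report, so exposure is
undefined).  χ² is the uncorrected Pearson statistic; a zero marginal gives
0.  A Yates-corrected variant is available behind a config flag but is not
the default, matching standard practice for PRR-based screens.

## The screen

Thresholds (PRR ≥ 2, A ≥ 3, χ² ≥ 4, boundaries inclusive) and the
candidate filter (≥ 100 co-mentions) and negative-evidence filter (≥ 500
co-mentions) are the conventional criteria for this family of screens and
are exposed in `ScreenConfig`.  Pairs are unordered and canonicalized by
sorted id everywhere; every statistic in the model is symmetric in the two
drugs, so this loses nothing.

## Propensity scores

Per drug, exposure is regressed on binary indicators of the top-100
indications and top-100 co-drugs ranked by φ = √(χ²/N), ties broken by
lexicographic id.  The fit is effectively unpenalized (L2 with C = 10⁸);
if any coefficient exceeds |30| — the practical symptom of quasi-complete
separation — the model is refit with a mild ridge (C = 10³) and flagged.
The propensity score enters the interaction model on the logit (linear
predictor) scale, not as a probability: the downstream model is itself
logistic, and the linear predictor preserves resolution in the tails.

## Interaction model and its penalty

For each screened (pair, PT), PT presence is regressed on
(PS₁, PS₂, Drug₁, Drug₂, Drug₁·Drug₂) with an L1 penalty on the slopes and
an unpenalized intercept.  The penalty path has 50 log-spaced values from
λ_max (the KKT bound that zeroes all slopes) down to 10⁻⁴λ_max, fitted
warm-started by an IRLS + coordinate-descent solver (`ddimine._l1path`)
that uses covariance updating: per quadratic approximation the weighted
Gram matrix of the six columns is accumulated once in O(np²), after which
each coordinate sweep costs O(p²).  Soft-thresholding produces exact
zeros, which the sign-based verdicts rely on; ε = 10⁻¹⁰ in the verdict
rules only guards float noise.  The solver is cross-checked against
scikit-learn's liblinear solutions in the unit tests (agreement to ~10⁻⁴
at matched penalties); a single solver fits one 50-point path over 120,000
reports in ~0.3–0.6 s, which is what makes per-(pair, PT) refitting over
hundreds of screened associations tractable on one CPU.

Two design choices here were settled by measurement on simulations with
planted, known interactions, and both differ from the most common default:

* **Scaling.** The two PS columns are centered and scaled; the three
  binary indicators are left on their natural 0/1 scale, so the penalty is
  paid per log-odds unit.  Scaling a rare indicator such as Drug₁·Drug₂ to
  unit variance makes its penalty cost roughly √(p(1−p)) ≈ 1/20 of a main
  effect's, and under that scaling the interaction coefficient absorbs
  small amounts of screen-selected noise almost for free: on simulated
  databases with no planted interaction the synergistic-call rate among
  screened associations was an order of magnitude above the natural-scale
  variant.
* **λ selection: one-standard-error rule.** λ is the largest value whose
  mean 3-fold CV deviance (folds stratified by PT presence) is within one
  standard error of the minimum.  Selecting the minimum itself degenerates
  here: with five predictors and ~10⁵ reports, held-out deviance is nearly
  monotone in model freedom, the chosen λ is close to zero, and the fit is
  essentially the MLE — whose interaction coefficient is positive for most
  screen-selected null associations precisely because the screen and the
  fit see the same data.  The one-SE rule restores the intended behavior:
  planted interactions with odds ratio 6 are recovered while the
  null/false synergistic-call rate stays within the few-percent range the
  acceptance suite asserts.  Both knobs are configurable
  (`LassoConfig(selection="min_cv", standardize_binary=True)`) for anyone
  wanting the plain-CV variant.

The model is fitted on *all* reports (not only reports mentioning one of
the two drugs); an optional seeded report subsample (`LassoConfig.subsample`)
exists as a tractability knob and defaults to off.  Whether the additive
verdict requires a passing screen is not forced by the verdict algebra; we
require it, since an additive call asserts a positive association that the
screen is there to establish.

## Integration and validation

"Linked" counts both synergistic and additive verdicts.  A negative pair
requires an explicit no-DDI verdict on every main and supporting PT of the
ADE; any undetermined verdict excludes the pair — a conservative reading
that keeps ambiguous pairs out of both classes.  The IS max-substitution
rule uses the maximum over the dataset's drug roster (a global database
maximum is not available by construction).  Validation uses the exact
Mann–Whitney U for the rank AUC and the two-sided rank-sum test for the
p-value.  A pair may be positive for one ADE and negative for another;
provenance strings record which PTs drove each label.

## Descriptors and the classifier

The per-target activity score is s = Pa/(Pa+Pi); Pa + Pi = 0 is an error
rather than a default, and drugs missing panel targets are rejected rather
than imputed.  The target ordering is frozen lexicographically at load and
fingerprinted (first 16 hex digits of a SHA-256); models store the
fingerprint and refuse probes built under a different order.

Forests use 500 trees, √p features per split, unlimited depth — the
defaults of the classical Random-Forest implementations.  M = 10
under-samples by default ("multiple" is not a number; it is configurable,
and evaluation-heavy tests use smaller M and tree counts, which can only
understate accuracy).  The ensemble probability is the arithmetic mean of
sub-model probabilities.

**Applicability domain.** The published "local (Tree)" criterion is not
restated in a reproducible form in the literature this package follows, so
the AD here is a documented stand-in in the same spirit: the standard
deviation of per-tree predicted probabilities pooled over all sub-models.
The threshold τ is the 0.95-quantile (configurable coverage) of training
pairs' *out-of-bag* dispersions — per pair, only votes of trees whose
bootstrap excluded it are pooled, using the forest's stored bootstrap
seeds.  Prediction-time dispersion uses all trees; the calibration/
prediction estimator mismatch is second-order (both are √-variances of the
same vote distribution) and is absorbed by choosing coverage on the
training set.

**Compound-out CV.**  Drugs are partitioned into k seeded sets; fold f
trains on pairs with both drugs outside set f and evaluates the pairs
whose lexicographically-first drug is in set f, so each pair is evaluated
exactly once and every evaluated pair contains a drug absent from all of
its fold's training pairs.  AUC is pooled over all test predictions;
sensitivity, specificity and balanced accuracy are computed at probability
0.5 on in-AD test pairs only, mirroring the convention of reporting
accuracy alongside AD coverage.  Folds whose training split loses a class
are skipped with a warning and recorded.

## Synthetic data: what it emulates, what it does not

The report generator reproduces the causal structure the method must
untangle — confounding by indication on both the exposure side
(indication → treating drug, log-odds 1.5) and the outcome side
(indication → PT, log-odds 1.0 for half the indications), individual drug
effects (log-odds 0.7 for 30% of drugs), and planted multiplicative
interactions that fire only when both pair drugs are present.  Defaults
are the study conditions the acceptance suite runs: 120,000 reports, 60
drugs, 30 indications, 24 PTs, 8 planted pairs at interaction odds ratio
6, seed 42.  Drug-set sizes are a by-product of independent Bernoulli
draws with mean 3 drugs/report; baseline PT rate is 2%; indication
prevalences are Beta(2, 28).  Every report receives one uniform
"background complaint" PT from the pool of PTs without planted
interactions, guaranteeing a nonempty reaction set without perturbing the
planted signals.

Not emulated: reporting biases (stimulated reporting, duplicates,
notoriety effects), report quality weights, dose, time-on-drug, and the
MedDRA hierarchy beyond explicit main/supporting lists.  Passing tests
therefore demonstrate statistical correctness of the machinery under a
known generative model, not robustness to FAERS-specific artifacts.

Target profiles are independent Beta(1.2, 3.5) draws for Pa and Pi — no
generative model of a real target predictor's output correlations is
attempted.  Mechanism labels threshold a sparse linear score over the pair
descriptor; the default sparsity 0.02 (8 active components at 200 targets)
encodes a mechanism carried by a handful of targets, which keeps the clean
labels essentially perfectly learnable — with balanced label-flip noise
ρ the oracle AUC is then capped at (1−ρ)² + ρ(1−ρ) (0.90 at ρ = 0.1), and
measured compound-out CV performance sits a few points below that ceiling.
Inference scores are Exponential(1) baselines plus an Exponential(effect)
bump for drugs of positive pairs; effect 0 gives exchangeable scores.

## Reproducibility

Every stochastic stage takes an explicit seed; the pipeline derives
per-stage seeds as SHA-256("seed:stage") mod 2³¹ and records them in the
run manifest together with a hash of the canonical configuration.  Two
runs with identical configuration and inputs produce byte-identical
tabular outputs (fixed sort orders, fixed float formatting via `repr`).

## Problem sizes used in the shipped checks

The test suite and acceptance script run the mining stage at the full
120,000-report study conditions; the type-I-control replicates use a
size-scaled copy (25,000 reports, 30 drugs, 16 PTs, 10 seeds) with all
rates and effect sizes unchanged; classifier evaluations use the
2000-pair / 80-drug / 200-target mechanism scale with M = 4 sub-models and
250 trees (accuracy-conservative relative to the 10 × 500 defaults).

## Known limitations

* The AD criterion is a stand-in for the published local-tree approach
  (see above); absolute AD coverage numbers are not comparable to reports
  using the original criterion.
* Verdicts inherit the screen's selection bias; the one-SE penalty rule
  controls but does not eliminate it (the acceptance suite quantifies the
  residual false-call rate on simulations).
* The loaders assume standardized identifiers; real FAERS/AEOLUS ingestion
  (de-duplication, name normalization) is explicitly out of scope.
* Propensity features are binary presence indicators; report-level
  covariates such as age, sex, or polypharmacy burden are not modeled.
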