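# Methods

This note documents the models behind `paikit`, the choices made where the
design was genuinely open, and what the validation suite does and does not
establish.

## Outcome definition: distress-change slopes

The analysis target is each participant's per-week rate of change in a
distress composite measured weekly at weeks 0–4.  `slopes.fit_random_slopes`
fits a linear growth model by REML with fixed effects for week (plus
arm×week when arm labels are supplied) and correlated person-level random
intercepts and slopes (unstructured 2×2 covariance, the standard default
for growth models).  A participant's slope is the fixed part plus their
empirical-Bayes (EB) random-slope deviation; EB estimates shrink noisy
individual trends toward the group mean, which reduces outcome noise
relative to per-person least squares without materially reordering
participants (rank correlation with per-person OLS is ≈0.99 on generator
data).  Assumptions: linear change over the observation window, Gaussian
residuals, exchangeable participants.  Participants with fewer than two
distinct observed weeks receive no slope and are excluded with a logged
count.  If the mixed model fails to converge — or converges with a
numerically zero residual variance, where shrinkage is vacuous — the
per-person OLS slopes are used instead and flagged in the `method` column.
Slopes are per week; a 4-week program effect is `4 × slope`.

## Arm-specific prognosis under nested cross-validation

Two elastic-net models are fit, one per arm, predicting slopes from the
encoded baseline table.  The objective is

    (1/2n)·RSS + λ(α‖β‖₁ + (1−α)/2‖β‖₂²),   intercept unpenalized.

`fit_enr` delegates the optimization to scikit-learn's coordinate descent
(tolerance 1e-8), with two exactly-solved special cases: λ=0 (least
squares) and α=0 (closed-form ridge with penalty n·λ).

Honest own-arm predictions come from nested CV: for each outer fold, inner
CV on the outer-training partition selects (α, λ), the model is refit on
the outer-training rows and scores the held-out fold.  No participant's
outcome influences the model that predicts it (verified by a perturbation
test).  Counterfactual predictions use the other arm's model fit on that
arm's full sample, with hyperparameters chosen by inner CV on the same
sample.

Defaults (all overridable through `ENRSettings`):

| parameter | default | rationale |
|---|---|---|
| α grid | 0, 0.1, …, 1.0 | spans ridge to lasso |
| λ path | 100 values, log-spaced 4 decades down from λ_max | glmnet convention; λ_max uses the α=0.001 surrogate for pure ridge |
| outer folds | 10 | common nested-CV default |
| inner folds | 10 | likewise |
| tie-break | larger λ, then smaller α | parsimony when CV errors tie |

Standardization statistics are recomputed inside each outer-training
partition and applied to its test fold, so no scaling information leaks
across folds.  Imputation (below) is pooled across the full baseline table
before any split — a deliberate mirror of the common single-imputation
workflow; the residual leakage this admits is limited to covariate
cross-information because the outcome is excluded from imputation by
construction.

## Preprocessing

Binary covariates are encoded as single 0/1 indicators; the 4-level income
variable is reference-coded into 3 indicators; continuous scores pass
through.  Unseen categories at scoring time raise rather than extrapolate.

Missing baseline values (the generator injects ~0.4% MCAR, matching a
trial where no variable missed more than 6 of 662 values) are imputed with
an iterative random-forest scheme in the missForest style: initialize with
column means/modes, revisit columns in increasing-missingness order fitting
a forest of each column on all others, and stop at the first increase of
the convergence criterion (normalized squared change for continuous
columns plus proportion-changed for categorical ones), returning the
previous iterate; cap at 10 sweeps.  Forests use 100 trees with
square-root feature subsampling; categorical columns use classification
forests (majority vote).  These sizes are conventional defaults — the
procedure is insensitive to them at the missingness rates involved.
Observed cells are never altered, and excluded columns (always id/arm,
plus anything passed in `excluded`, e.g. an outcome) are neither imputed
nor used as features.

## PAI, moderation, and recommendation zones

`PAI = predicted treatment slope − predicted control slope`; negative
favors treatment.  Recommendations use a threshold of 0 with ties going to
control (conservative).  The evaluation regresses the observed slope on
`group + PAI + group×PAI` by OLS (group coded control=0, treatment=1; PAI
uncentered), reporting the interaction t, residual df, p, and adjusted r².
An optional covariate block supports sensitivity analyses such as
adjusting for baseline depressive symptoms.

Geometry on the PAI axis:

- **Intersection** x\* = −(a_t − a_c)/(b_t − b_c) of the two arm lines;
  parallel lines (|Δb| < 1e-12) raise an explicit error.
- **Bootstrap CI**: rows resampled with replacement B=1000 times, the
  interaction model refit, the intersection recomputed; percentile
  interval at 95%.  Replicates with a single-valued group or near-parallel
  lines are counted degenerate and dropped; a CI built from fewer than
  B/2 finite replicates is flagged unreliable.  The left margin is the
  decision boundary.
- **Johnson–Neyman**: the conditional group difference at PAI=x is
  g + b_int·x with variance v_g + 2x·cov + x²·v_int; boundaries solve
  t(x)² = t²_crit with the interaction model's residual df (quadratic in
  x, solved in closed form and reported within the observed PAI range,
  each sub-interval flagged significant or not).  The boundary used for
  zoning is the largest significant-side boundary at or below the
  intersection.

Zones: red at or right of the intersection (control predicted no worse);
green strictly left of both the CI margin and the JN boundary; yellow
between.  The intersection dominates if the landmarks are ever disordered,
keeping the partition exhaustive and mutually exclusive; without a JN
boundary the zones degrade to yellow/red with a warning.

Percentile translation assumes slopes are per-week over a 4-week program
and maps through the standard normal CDF: starting percentile → z, plus
`weeks × slope / baseline SD`, → percentile (rounded to an integer).  The
default baseline SD 0.895 pools arm SDs of 0.88 (n=342) and 0.91 (n=315).
A normal approximation is used rather than empirical percentiles.

The comparison model repeats the construction with a single predictor and
plain simple regression per arm, out-of-fold under 10-fold CV repeated 100
times with predictions averaged across repeats, counterfactuals from the
full other-arm regression.

## Power simulation

`power.simulate_interaction_power` draws, per replicate, a median-split
binary group x1 (latent-normal threshold; the point-biserial correlation
of a median split is attenuated by √(2/π), which the latent correlation
compensates for), a continuous moderator x2, and
`y = b1·x1s + b2·x2 + β₃·x1s·x2 + e` with b1, b2 solved from the target
simple correlations and e scaled so var(y)=1, then fits the interaction
model by OLS and records rejection at α.  `min_sample_size` bisects over n.
Infeasible correlation structures are rejected before simulation.  The
effect-size inputs behind any particular published sample-size figure are
study-specific and not derivable from summary statistics alone; the
module therefore ships a documented example specification
(`power.example_spec`) rather than claiming to reproduce one.

## The synthetic trial generator

The generator emulates a two-arm meditation-app trial in a distressed but
subclinical adult workforce: 12 continuous questionnaire scores (distress
composite standardized at baseline; PROMIS-style T-scores for depression
and anxiety; conventional scales otherwise), age, three binary demographic
fields, a 4-level income variable, 1:1 permutation-based allocation,
weekly distress at weeks 0–4, and sparse MCAR missingness (rate 0.004,
i.e. ≲6 values per column at n=662).

Continuous covariates come from a Gaussian copula and are rescaled to the
target means/SDs; the default correlation matrix is a single-factor
structure (general-distress loadings 0.9 down to −0.6) producing a
0.3–0.7 correlation block among symptom measures and negative correlations
with the mindfulness/wellbeing scales.  This structure is *illustrative* —
chosen to be plausible, PSD by construction, and easy to reason about —
not estimated from any dataset.  Likert-bounded scales are not truncated,
preserving the correlation targets.  Binary/ordinal fields threshold
independent latent normals at the quantiles of their category
probabilities.

True slopes are linear in the standardized covariates with arm-specific
coefficients, an arm main effect of −0.07 slope units (treatment improves
faster), a shared person-level slope deviation (SD 0.05), and week-level
measurement noise (SD 0.15).  The default coefficient vectors follow the
qualitative pattern reported for this kind of trial — higher baseline
symptoms predict larger reductions in both arms, while repetitive negative
thinking predicts *better* outcomes under treatment and *worse* outcomes
under control — with magnitudes scaled so that moderation is detectable at
n=600 (advantage SD ≈ 0.06–0.08, per-arm prognostic R² ≈ 0.3–0.4).  A real
trial of this kind shows weaker signal (prediction r ≈ 0.2–0.3); the
stronger defaults make ground-truth recovery tests informative at desk
scale and are not a claim about effect sizes in the field.  Both
counterfactual slopes are generated for every participant (the person
deviation is shared across arms), so the true individual advantage
`slope_T − slope_C` is known exactly and noise-free.

Named random substreams (covariates / arms / trajectories / missingness)
hang off the config seed, so toggling one stage never shifts another, and
identical configs produce byte-identical CSVs.

What the generator does *not* emulate: MAR/MNAR missingness, dropout,
item-level responses or computer-adaptive scoring, floor/ceiling effects,
nonlinear change, or site/cluster structure.  Passing recovery tests on
this generator therefore shows the pipeline's statistical machinery is
correct under its stated model — not that a real trial of this size would
yield comparable prediction accuracy.

## Numerical choices

- Elastic-net coordinate descent tolerance 1e-8 (1e-7 with warm starts
  inside the hyperparameter search, where ranking — not the last digit —
  matters); λ=0 and α=0 solved exactly.
- Inner-CV ties (relative 1e-12) break toward larger λ, then smaller α.
- Zero-variance continuous columns are dropped during standardization with
  a logged warning and recorded in the stats object; a zero-variance
  outcome in an outer-training fold logs a warning but fits proceed.
- The moderation model requires n ≥ terms + 2 (at least 2 residual df);
  constant PAI or single-valued group raise immediately.
- Bootstrap replicates with |Δslope| < 1e-12 are treated as parallel.
- All simulation entry points accept either a `numpy` Generator or an
  integer seed; the pipeline fans a single root seed into per-stage
  substreams recorded in the manifest.

## Validation suite problem sizes

The simulation-heavy checks run at sizes chosen to keep the full suite at
desk scale while leaving the statistical conclusions unchanged: recovery
uses 20 seeds × n=600 with a reduced search grid (α ∈ {0, 0.5, 1}, 20-value
λ path, 5 outer / 3 inner folds) and 50-tree imputation; null calibration
uses 1000 replicates at n=300 with a single-α grid; bootstrap coverage
uses 500 datasets × B=1000.  The pipeline defaults stay at the full grids.

## Known limitations

- **Null calibration of the two-model CV construction.**  The moderation
  test applied to a PAI built from out-of-fold own-arm predictions is
  *anticonservative under the null*.  Mechanism: an out-of-fold prediction
  carries its training partition's intercept, essentially mean(y) over the
  fold complement, whose deviation from the grand mean is exactly
  −n_f/(n−n_f) times the held-out fold's mean-y deviation.  The PAI
  therefore encodes fold means of the outcome, with opposite signs in the
  two arms (the own-arm prediction enters the difference with a different
  sign for treated and control participants), which deterministically
  pushes the group×PAI interaction negative when the predictors carry no
  signal.  The effect grows with the number of folds (mean interaction
  t ≈ −1.8 at 5 outer folds and ≈ −2.6 at 10, versus 0 for a calibrated
  test; two-sided rejection ≈ 47% at 5 folds instead of 5% in this
  package's calibration suite), and averaging over repeated fold
  partitions converges toward leave-one-out intercepts, which makes it
  worse rather than better.  The OLS interaction test itself is calibrated
  when the moderator is exogenous (4.65% empirical size over 2000 null
  replicates).  Consequences: a significant *negative* interaction can be
  produced by the construction alone and should not be interpreted; a
  significant *positive* interaction (the direction that validates the
  PAI) is working against this bias and is therefore conservative.  The
  calibration test in `tests/test_acceptance.py` documents the measured
  rate and intentionally asserts the ideal 5% band, so it fails until a
  construction without this artifact exists.
- Pooled imputation before CV admits covariate-level information leakage
  across folds (the outcome is excluded, bounding the optimism).
- The EB slopes feed later stages as fixed quantities; their estimation
  uncertainty is not propagated into the prognosis or moderation standard
  errors.
- The percentile translation assumes normally distributed baseline scores
  and a constant within-person slope.
- The per-arm mixed-model option estimates variance components on half the
  data and can over-shrink in small arms; the joint fit is the default.
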