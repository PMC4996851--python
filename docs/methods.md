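# Methods

`coxbench` benchmarks strategies for estimating a Cox proportional-hazards
prognostic model when events are scarce relative to the number of candidate
predictors (low events-per-variable, EPV).  The package implements the full
loop: synthetic cohort → Weibull truth model → censored survival data at a
target EPV → six estimation strategies → truth-based scoring → replicated
aggregation.  This note records the model, the defaults and why they were
chosen, the numerical choices, and the limits of what the synthetic study
can show.

## Data-generating model

The truth is a Weibull proportional-hazards model.  We fix the
parameterization explicitly, since several conventions coexist:

    h0(t) = rate * shape * t^(shape-1),       S0(t) = exp(-rate * t^shape)
    S_i(t) = exp(-rate * t^shape * exp(x_i' beta))

Event times are drawn by the inverse-transform method for proportional
hazards: with U ~ Uniform(0,1),

    T_i = ( -log U_i / (rate * exp(x_i' beta)) )^(1/shape).

Right-censoring is uniform on (0, delta): each individual's follow-up is
cut at an independent U(0, delta) draw, so smaller delta yields fewer
observed events and realized follow-up never exceeds delta.  No additional
administrative censoring is applied.

`delta` is calibrated analytically: the expected event count
`sum_i (1/delta) * int_0^delta F_i(u) du` is evaluated by adaptive
quadrature and solved for the target `EPV * p_candidates` by bracketed
root finding (tolerance 0.1 expected events).  The EPV denominator is the
number of *candidate* predictors of the scenario (9 or 64), not the number
retained by selection.  Calibration is deterministic and independent of
simulation seeds.

## Synthetic cohorts

Two built-in scenarios mimic a secondary-prevention coronary-artery-disease
cohort.  Scenario 1 has 9 clinical/biomarker predictors; scenario 2 adds 55
allele-dosage variants (51 SNPs, 4 indels).  Only two summary anchors of
the motivating population are public — median age near 63 years and 77.6%
male — so the remaining marginals are plausible defaults, all overridable:

| column | distribution | default |
|---|---|---|
| age | Normal | mean 63, SD 10 years |
| male | Bernoulli | 0.776 |
| BMI | Normal | mean 27, SD 4 kg/m² |
| LDL/HDL ratio | LogNormal | median 2.5, log-SD 0.35 |
| current smoking | Bernoulli | 0.20 |
| diabetes | Bernoulli | 0.25 |
| hypertension | Bernoulli | 0.80 |
| C-reactive protein | LogNormal | median 2 mg/L, log-SD 1.0 |
| creatinine | LogNormal | median 1 mg/dL, log-SD 0.2 |
| 55 variants | 2 × Bernoulli(freq) | freq ~ U(0.05, 0.5), fixed by a built-in seed |

Mild co-morbidity structure (e.g. BMI–diabetes rank correlation 0.25,
age–hypertension 0.20) is induced in the clinical block through a Gaussian
copula on the rank scale (latent Pearson correlation `2 sin(pi rho_s / 6)`);
variants are independent — no linkage disequilibrium is simulated, because
none is published for the motivating panel and independence is the simplest
testable default.  Dosages are hard calls (sums of two Bernoulli allele
draws), without imputation-dosage noise.

True coefficients are drawn once per experiment: N(0, effect_scale²) on the
standardized scale, clipped at ±3·effect_scale, then divided by each
column's marginal SD so that a one-SD change in any predictor moves the
linear predictor comparably.  The default `effect_scale = 0.2` gives a
linear-predictor SD near 0.6 — moderate, realistic prognostic signal
(truth-vs-estimate concordance in the 0.75–0.86 range at EPV 2.5–10).

Two truth routes exist: `direct` (the drawn coefficients are the truth) and
`fit_from_source`, which simulates a well-powered source outcome and lets a
ridge-penalized Weibull fit to it play the truth role — the two-step design
used when the truth is derived from a real cohort.  `direct` is the default
because it makes every downstream quantity exactly known.

### Baseline anchoring

Because the covariates are not centered, a drawn beta implies an arbitrary
mean linear predictor, which would rescale the marginal event rate — and
hence the calibrated censoring horizon — at random.  The experiment
therefore divides the configured rate by `mean(exp(X beta))`, making `rate`
the cohort-average rate.  Scenario defaults are shape 1.1 with rate
0.08/year (scenario 1) and 0.03/year (scenario 2), chosen so that the
calibrated delta at the lowest EPV level (2.5) still spans the scenario's
largest evaluation timepoint; evaluation timepoints are 0.08/0.17/0.25
years (scenario 1) and 1/2.5/5 years (scenario 2).

## Estimation strategies

All six strategies share a Breslow partial-likelihood core.  Ties are
handled by the Breslow approximation everywhere; simulated times are
continuous so ties have probability zero, and Breslow keeps the
lambda → 0 limit of the penalized solver consistent with the full model.

* **full** — Newton–Raphson with step halving; convergence when the score
  sup-norm is ≤ 1e-8.  A coefficient exceeding |beta| = 50 flags
  monotone-likelihood divergence (`converged = False`) instead of raising,
  so replicate accounting can count such fits.
* **BE 0.05 / BE 0.5** — backward elimination: refit, drop the single
  predictor with the largest p-value while it exceeds the significance
  level.  Wald p-values from the inverse observed information are the
  default (a likelihood-ratio variant is available); the refit happens
  after every single drop.  An empty final set is a constant-prediction
  model — effectively a Kaplan–Meier-like estimator.
* **ridge / lasso / elastic net** — maximize the scaled penalized partial
  log-likelihood

      (2/n) l(beta) - lambda [ a ||beta||_1 + (1-a)/2 ||beta||_2^2 ],

  by outer iteratively-reweighted quadratic approximation (diagonal
  curvature) and inner cyclic coordinate descent with soft-thresholding,
  warm-started along a decreasing lambda path.  Covariates are standardized
  internally (mean 0, population variance 1); returned coefficients are on
  the original scale.  One printed form of this objective multiplies the
  log-likelihood by `2n`; the `2/n` scaling is adopted here — it is the
  convention under which the lambda path below is finite and standard.
* **BE + ridge** — backward elimination followed by a CV-tuned ridge refit
  restricted to the selected predictors (constant prediction if the
  selection is empty).

### Lambda path and tuning

`lambda_max = max_j |(2/n) dl/dbeta_j(0)| / a` on the standardized scale
(all coefficients are exactly zero there); the pure-ridge path uses the
`a = 0.001` value of the formula (a 1000-fold inflation).  The grid is
log-spaced with a per-step factor anchored so the default span
(`lambda_min_ratio = 1e-4`, the n > p convention) holds exactly 100 points;
passing a smaller ratio extends the grid downward without changing the
upper entries.  A ratio of 0.01 was considered and rejected: combined with
the 1000-fold ridge inflation it would leave the entire ridge path heavily
shrunk even at EPV 10.

The tuning parameter maximizes the cross-validated partial log-likelihood
(Verweij–van Houwelingen):

    CV(lambda) = sum_k [ l_all(beta^(-k)) - l_(-k)(beta^(-k)) ],

with 10 folds by default (5 supported), no one-standard-error rule, and
for the elastic net a mixing grid 0, 0.05, …, 1.  Fold membership is
uniform-random by default; a predictor-balanced variant clusters
individuals with K-means on standardized predictors and deals each
cluster's members evenly across folds.  Within a replicate all penalized
methods see the same folds.

Fold fits along the path run in *path-tracking mode* — three reweighting
passes of at most two coordinate-descent sweeps per lambda, riding the warm
starts — which reproduces the fully converged CV argmax (47/48 exact, one
adjacent grid point, in a 48-combination audit) at a fraction of the cost.
The final model is always refit on all data to full convergence
(coefficient tolerance 1e-9) at the chosen (a, lambda).

## Scoring against the truth

Predictions use the Breslow baseline cumulative hazard at the fitted
coefficients; before the first observed event H0 is exactly zero (predicted
survival exactly 1), and beyond the last event the last step value is
carried forward (no hazard extrapolation).

* **RMSE(t)** = sqrt( mean_i (S_i(t) − Ŝ_i(t))² ), computable for every
  fit, degenerate or not.
* **Calibration slope** — OLS slope of true event log-odds on predicted
  event log-odds.  1 is ideal; < 1 means overfitting, > 1 means
  over-shrinkage.  The three evaluation timepoints are pooled into one
  regression (per-timepoint slopes are also emitted); NA if any predicted
  probability is exactly 0 or 1 (log-odds diverge) or the predictions are
  constant.
* **Concordance vs truth** — share of individual pairs whose predicted
  event-probability ordering matches the true ordering; predicted ties
  score 1/2, pairs with tied true probabilities are excluded.  Computed at
  a single timepoint (it is ranking-invariant across timepoints), with
  tau = 2(concordance − 0.5).

Replicate accounting: a method's replicate enters the metric summaries only
when both the slope and the concordance were computable; RMSE is stored for
every replicate and the filter is applied at aggregation.  Summaries report
mean, 5%-per-tail trimmed mean, median, IQR, the usable count, and the
fractions of replicates with no variable selected, constant predictions,
or a predicted probability of one.

## Determinism

Every random draw descends from `master_seed` through named
`SeedSequence` spawn keys `(scenario, epv, replicate, stage)`; two runs of
an identical configuration are bit-identical, and all methods within a
replicate see the same data and folds.  The cohort and truth model are
generated once per experiment and held fixed; only event times and
censoring are redrawn per replicate, matching a design in which the
covariates are a fixed cohort.

## Problem sizes

The default configuration is n = 1731 individuals and 1000 replicates per
scenario × EPV cell.  The packaged direction-level study (test suite) uses
n = 1000, 100 replicates and EPV ∈ {2.5, 10} — sizes at which the
qualitative orderings (RMSE decreasing in EPV; penalized methods beating
the full model at EPV 2.5; BE 0.05 emptying more often than BE 0.5) are
already stable.

## What passing tests do and do not show

The generator reproduces marginal summaries, a plausible correlation
structure, and the low-EPV failure modes (monotone likelihood, empty
selections, probability-one predictions).  It does not reproduce the
motivating cohort's exact covariate distributions, linkage disequilibrium,
measured-biomarker tails, or its cohort-fitted truth coefficients — so
quantitative figures (absolute RMSE levels, Table-style usable counts)
are expected to differ from any real-cohort-derived study, while the
method *orderings* are the reproducible content.  Deviations of real
survival data from the Weibull form are likewise outside the model family
by construction.

## Known limitations

* No competing risks, covariate-dependent censoring, time-varying effects,
  stratification, or Efron tie handling.
* BE's p-value flavor (Wald) is a choice; likelihood-ratio BE is available
  but not the default.
* The diagonal-curvature IRLS can need many passes near lambda = 0 on
  strongly correlated designs; the full-model Newton solver is the
  reference there (the two agree to 1e-5 at lambda = 0 by test).
* The calibration slope pools timepoints; per-timepoint slopes are emitted
  for users who prefer averaging.
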