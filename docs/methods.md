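# Methods

This note documents the models, estimation machinery, synthetic-data
assumptions and numerical choices behind `riskadapt`, in the order the
pipeline uses them.

## Decision model

A gamble is (win probability `p`, win magnitude, loss magnitude); on each
trial the agent values the two displayed options as

    U = p · M_rew − (λ + γ · PrevOutc) · (1 − p) · M_loss

and chooses left with probability `1 / (1 + exp(β (U_right − U_left)))`.

* `PrevOutc` is coded **+1 after a win, −1 after a loss, 0 on a session's
  first trial**. The symmetric ±1 coding keeps λ the midpoint loss weight
  and makes γ > 0 mean "more loss-avoidant after a win". A continuous
  (points-valued) coding of the previous outcome is a plausible
  alternative; the binary coding is the package's convention and the
  generator and fitter share it, so the choice cannot bias recovery
  studies. History does not carry across sessions: sessions are separated
  by about a day and the model describes within-session sequential
  effects.
* Utilities are in **raw points**, so β has units 1/points. β = 0.1
  means a 10-point utility gap moves choice probability from 0.5 to 0.73.
* λ and γ are unbounded; the effective loss weight λ + γ·PrevOutc may go
  negative (loss seeking), which the model deliberately permits.

Numerics: the softmax logit is clipped at |β·ΔU| = 500 before
exponentiation, and per-trial probabilities are floored at 1e−12 inside
the log-likelihood. Neither bound is reachable with task-scale inputs
(|ΔU| ≤ ~400 points, β ≲ 10); they only guard pathological parameter
proposals during optimisation/sampling. The likelihood recomputes the
previous-outcome chain from the recorded outcomes and treats any mismatch
with stored values as a data-integrity error rather than repairing it.

## Stimulus generation

The experiment's design property is that most pairs are nearly tied in
expected value (EV = p·M_rew − (1−p)·M_loss): calibration targets are
**76% of pairs within 5 points and 90% within 20 points** of absolute EV
difference. The generator draws both options uniformly from the attribute
grids (magnitudes: multiples of 10 in 10–200; win probabilities: 0.05
grid in 0.05–0.95) and uses stratified rejection into three |ΔEV| strata
(≤5, 5–20, >20) with mixture weights (0.76, 0.14, 0.10). This reproduces
the published gap distribution without claiming to reconstruct the
original (unpublished) stimulus algorithm; all emitted attributes stay on
the grids. Infeasible targets (fraction ≤5 exceeding fraction ≤20) are
rejected at configuration time.

## Synthetic cohorts

`CohortConfig` defaults encode the study design the package emulates:

* groups low-MDQ (n = 37), high-MDQ (n = 40), BD-lithium (n = 19),
  BD-placebo (n = 16); volunteers play 50 daily sessions, patients a
  14-day baseline plus 42 post-randomisation days; 20 trials/session.
* participant-level (λ, γ, log β) are Normal per gradient group (β on the
  log scale for positivity); session-level values add Normal jitter and an
  optional linear day drift. Default group means: λ (1.1, 1.0, 0.7) — a
  step decrease in the patient group; γ (0.15, 0.08, 0.0) — monotone
  decline of the outcome-history effect along the gradient; log β
  (−3.2, −3.3, −3.5). The β level was calibrated so that model
  predictive accuracy on synthetic cohorts sits near the ~71% regime
  reported for human play of this task; γ and λ orderings mirror the
  qualitative group differences the analyses are designed to detect.
* between- vs within-participant SDs: λ 0.6/0.8, γ 0.15/0.3,
  log β 0.5/0.4. Session-to-session variability is set larger than
  between-participant spread for λ and γ: daily at-home behaviour is
  noisy relative to stable trait differences, and 20-trial sessions are
  the regime in which the dispersion submodel and the poor recovery of
  session-level SDs matter.
* lithium effects default to **0** on all three parameters (the study
  design this emulates found no drug effect on task parameters); power
  studies switch them on explicitly.
* mood: PANAS-positive/negative daily scores are participant baselines
  plus Normal noise whose SD rises along the gradient
  (pos (2.0, 2.5, 3.0); neg (1.5, 2.2, 3.0)) — mood instability is a
  group property. The happiness VAS (0–100) is rated before and after
  each session; the post rating moves by **0.4 VAS points per SD of the
  session's summed net outcome** (cohort-standardized) plus noise (SD 1).
  Same-day positive mood (within-person z-score) shifts that session's
  log β by (0.0, 0.1, 0.2) per gradient group — good-mood days mean more
  consistent choices, increasingly so along the gradient.

What the generator does **not** emulate: learning within or across
sessions, reaction times, dropout beyond missing-at-random, integer
rounding of mood scales, day-of-week or time-of-day structure, and any
feedback from behaviour to mood. Passing tests therefore demonstrate that
the estimators recover the data-generating process under these idealised
conditions, not that the same effect sizes hold in human data.

## Per-session fitting

Priors (Normal): λ ~ N(1, 1); γ ~ N(0, 0.5); log β ~ N(log 0.1, 1).
Centres are the "null" parameter values (symmetry, no history effect);
the β prior centre gives a 0.27→0.73 choice swing over a 10-point gap,
matched to the near-tied stimulus design. β is estimated on the log
scale.

Two engines:

* **MAP + Laplace** (default for batch runs): L-BFGS with analytic
  gradients on the 3-parameter negative log posterior; the posterior
  covariance is the inverse Hessian (central finite differences of the
  gradient); 95% intervals are mean ± 1.96 SD on the estimation scale and
  back-transformed for β (log-normal summaries, the reported β mean
  clamped into its own interval for consistency when the log-scale SD is
  large). A non-positive-definite Hessian is flagged as non-convergence.
* **Ensemble MCMC** (emcee): walkers initialised at the MAP with small
  jitter; default 16 walkers × 750 steps, 250 burn-in; summaries from the
  pooled post-burn draws; convergence flagged by max split R-hat < 1.1
  (walkers treated as chains — conservative for an interacting ensemble).
  Seeded and exactly reproducible.

With 20 trials the posterior is visibly skewed (mode ≠ mean, especially
for log β), so the two engines agree on posterior mass, not on point
estimates; the test suite asserts the MAP lies inside the sampled 95%
interval.

Validation harness: `parameter_recovery` simulates sessions from known
parameters (drawn from the priors by default), refits, and reports
Pearson correlation, bias and RMSE per parameter (β scored on the log
scale, the scale on which it is estimated and regressed). At 20
trials/session the point estimates of λ, γ, log β recover well
(correlations ≳ 0.6–0.85 at the default conditions) and improve
monotonically with trial count; session-to-session SDs of parameters are
*not* a validated quantity at 20 trials — the dispersion analyses are
reported but should be read with that caveat. `compare_models`
cross-validates nested variants (full; γ≡0; λ≡1; β-only) with 5
interleaved trial folds per session and ranks them by held-out
log-likelihood, also reporting held-out predictive accuracy (ties at
p = 0.5 count ½).

## Model-free statistics

Displayed utilities (loss weight 1, no history term) define the binning
axes. Choice curves use equal-count (quantile) bins, default 7 — the
granularity at which such curves are usually displayed; a 2-bin curve
equals a plain contingency computation, which the tests exploit as an
oracle. Dimension sensitivity fits, per participant, a logistic
regression of choosing left on the win-utility and loss-utility
differences jointly; the loss slope is sign-oriented so that λ = 1 means
equal win and loss slopes. The outcome-history contrast restricts to
non-first trials in the top 25% (configurable) of |loss-utility
difference| — a multiplicative change of the loss weight moves choices
most where the options' loss utilities differ most — labels the
lower-loss option (ties excluded: the label is undefined), and reports
P(choose lower-loss | previous win) − P(choose lower-loss | previous
loss). Participants with an empty conditional cell are flagged, not
silently dropped. The extreme-trial threshold is a dataset-wide quantile
(per-participant thresholds would entangle the statistic with each
participant's stimulus draw).

## Group inference

Ordered groups are coded with orthonormal polynomial contrasts (k = 3:
linear (−1, 0, 1)/√2 and quadratic (1, −2, 1)/√6). The linear
coefficient is "the gradient"; the quadratic absorbs step asymmetry, so a
pure patient-group step change loads on both. Coding depends only on the
level order, never on label strings.

Session-wise outcomes enter a Gaussian **location-scale** model: mean =
intercept + day (centered per participant) + gradient codes + age
(z-scored) + gender (centered ±½) with per-participant random intercepts
and day slopes; log σ = intercept + gradient codes + age + gender with
per-participant random intercepts. The log link keeps σ positive. The
drug analysis replaces the gradient terms with arm (±½), phase (±½),
their interaction (the reported effect) and the baseline-length covariate
(dropped automatically when constant).

Estimation is **empirical-Bayes MAP + Laplace**:

1. Variance components (τ of each random effect) are estimated by the
   method of moments on per-participant OLS fits — between-participant
   variance of intercepts/slopes/log residual SDs minus their average
   sampling variance, floored at small positive values (5% of the
   outcome SD) so the conditional posterior stays proper when a component
   is genuinely zero.
2. Conditional on τ, all fixed and random effects are jointly optimised
   (L-BFGS, analytic gradients) under wide Normal priors
   (coefficients N(0, 10·SD(y)); log-scale coefficients N(0, 5)); the
   Laplace covariance of the full parameter block yields fixed-effect
   SDs that propagate random-effect uncertainty given τ.

Jointly maximising τ with its own effects is *not* done: that joint
posterior is unbounded as τ → 0 (the hierarchical funnel) and its "mode"
is meaningless. The plug-in approach mirrors standard mixed-model
practice (REML point estimates of variance components with Wald
intervals); its known cost is mild undercoverage because τ uncertainty is
ignored — simulation at the default cohort size puts the realised
coverage of the nominal 95% gradient interval at roughly 90–94%. With no
random effects and the dispersion submodel disabled the machinery reduces
to (essentially) OLS, which the tests verify against statsmodels.

Decision rule: central 95% interval excluding zero, no multiplicity
correction (matching the credible-interval convention of the analyses
this package implements). Age and gender are controlled in both
submodels; day is centered within participant for sampler-free stability
of the intercept.

## Mood analyses

* **Instability** = sample SD of a participant's daily PANAS series
  (≥3 days required; shift-invariant by construction); group comparison
  via the (non-hierarchical) gradient regression, since there is one SD
  per participant.
* **Happiness coupling**: ΔVAS (post − pre) regressed on the
  cohort-standardized session net outcome with gradient main effects, a
  net-outcome × linear-gradient interaction, age/gender, and random
  intercepts. Constant net outcomes make the coupling unidentifiable and
  raise an error.
* **Mood → noisiness**: session log β regressed on same-day
  positive-PANAS (standardized *within* participant, so the daily
  coefficient is not confounded by stable between-person mood
  differences) with a gradient interaction and random
  intercepts/slopes; and, across participants, mean log β on the
  mood-instability SD. Participants with fewer than 2 mood days are
  excluded from the daily analysis with a warning.

## Pipeline and reproducibility

One master seed spawns independent per-stage seeds
(`numpy.random.SeedSequence`); the manifest records the config hash and
all stage seeds. Reruns with identical configs reproduce all CSV outputs
byte for byte (figures are regenerated but not part of the determinism
contract). Stage failures abort with the stage name; downstream stages
refuse to run without their inputs.

## Problem sizes used in the shipped studies

Validation studies in the test suite run at sizes chosen to make their
statistical targets well-resolved while staying desk-scale: recovery at
100 sessions × 20 and 200 trials; model identification over 20 replicate
20-session cohorts; gradient calibration over 50 null and 20 shifted
cohorts at the full default group sizes (using the generator's
session-wise ground-truth parameters as the regression outcome, which
isolates the inference layer being calibrated); the model-free sign
study over 60-participant single-group cohorts per γ value. The power
condition of the gradient study shifts γ by 0.2 × the session-wise SD
(√(between² + within²)) per group step.

## Known limitations

* Laplace summaries are Gaussian approximations; for 20-trial sessions
  the MCMC engine is the reference when interval shape matters.
* Plug-in variance components (above) mildly understate fixed-effect
  uncertainty; dispersion-submodel contrasts inherit the 20-trial
  caveat on session-level SDs.
* The generator's mood model is a stationary Gaussian process around a
  fixed baseline; it cannot produce episodes, trends, or autocorrelated
  mood, so mood analyses here validate estimator correctness, not
  clinical dynamics.
* Model comparison uses within-session cross-validation; it does not
  address transfer across sessions or participants.
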