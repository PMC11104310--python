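# Methods

## Task and outcome coding

The orthogonalized Go/No-Go task crosses required action (go / no-go) with
outcome valence (win / avoid-loss): GO_WIN, NOGO_WIN, GO_AVOID, NOGO_AVOID.
GO_WIN and NOGO_AVOID are Pavlovian-congruent. Schedules interleave the four
conditions in randomized blocks of four (one trial of each per block), which
bounds local imbalance and stabilizes binned learning curves; the default
administration is 60 trials per condition (240 total), repeated over five
administrations.

Outcomes are coded {+1 reward, 0 neutral, −1 loss}. Two outcome rules are
implemented because the task's verbal description and its model description
disagree about win-condition errors:

- `paper_text` (default): the correct action yields the better outcome with
  probability 0.8; in *win* conditions the wrong action yields a **loss**
  with probability 0.8 (and a reward otherwise); in loss conditions the
  wrong action yields a loss with probability 0.8 (and nothing otherwise).
- `conventional`: win conditions only ever deliver reward/nothing, loss
  conditions loss/nothing.

Both satisfy the invariant that the correct action gives the better outcome
with the dominant probability. The variant is a config switch
(`outcome_rule_variant`) rather than a silent choice, so sensitivity to the
coding can be tested directly.

Responses after the 1.5 s deadline are flagged `missed`, treated as no-go
for learning and accuracy, and excluded from reaction-time summaries.

## The model family

Choice follows a two-action softmax over a go and a no-go value, optionally
mixed with uniform noise: `p ← p·(1−ξ) + ξ/2`. Values combine:

- instrumental learning `Q(a,s) ← Q(a,s) + α(βr − Q(a,s))` — β scales the
  reinforcement *inside* the delta rule (it is not a softmax temperature),
  so |Q| is bounded by β;
- a fixed additive go bias `b`;
- a Pavlovian stimulus value `V(s) ← V(s) + α(βr − V(s))`, learned
  irrespective of the action taken, contributing `π·V(s)` to the **go**
  value only. Negative V (loss stimuli) therefore suppresses going; V never
  boosts withholding directly.

The canonical nested family is `RW`, `RW+noise`, `RW+noise+bias`,
`RW+noise+bias+Pav` (one π), `RW+noise+bias+2Pav` (π⁺ for win-valence
stimuli, π⁻ for loss-valence stimuli), and `RW+noise+bias+2Pav+session`,
in which π⁺ may take a different value from administration 3 onward and π⁻
from administration 4 onward, mirroring the appetitive and aversive therapy
phases. All other parameters are shared across administrations within
subject. Exploratory valence-specific learning-rate and noise variants
exist behind `ModelSpec` flags but are off by default.

Design choices the task description leaves open:

- **Dual-Pavlovian gating** is by condition valence, not by the sign of the
  learned V, which fluctuates early in learning; valence gating is
  deterministic and matches the appetitive/aversive stimulus distinction.
- **State resets to zero** at the start of every administration: each
  administration uses fresh stimuli, so carrying values over would be
  incoherent.
- α and β are shared between Q and V learning.

Parameters live on natural scales (α, ξ ∈ (0,1); β > 0; b, π ∈ ℝ) and are
fitted on an unconstrained scale via logit/log transforms; the transform
pair is an exact bijection (round-trip tested to 1e-10).

## Hierarchical fitting and model comparison

Subjects share an independent (diagonal) Gaussian prior over transformed
parameters — the standard choice in this literature, and the only stable
one at cohort sizes near 12. Fitting is empirical-Bayes EM:

- **E-step**: per-subject MAP by L-BFGS (best of several restarts drawn
  from the prior, warm-started from the previous iteration), with a
  central-difference Hessian at the mode, eigenvalue-clipped to positive
  definite (floor 1e-6), giving a Laplace approximation of each posterior.
- **M-step**: prior mean = mean of MAPs; prior variance = mean(MAP² +
  posterior variance) − mean(MAP)², floored at 1e-6.
- Convergence when the largest prior-mean change is below `tol`
  (default 1e-3, max 50 iterations). The surrogate objective (sum of
  Laplace log marginals) is monitored; a decrease above 0.5 nats aborts
  with diagnostics.

The integrated BIC is `−2·Σᵢ log p(dataᵢ | prior) + 2k·log(N)`, with the
per-subject marginal estimated by Monte-Carlo averaging of likelihoods over
draws from the fitted prior (log-sum-exp stabilized; 2000 draws by
default), k the number of model parameters (the prior carries a mean and a
variance per parameter, hence the factor 2), and N the total number of
choices. Absolute iBIC values depend on the sampling settings; ΔiBIC
rankings are the reproducible object, and model-recovery tests assert
rankings only. Posterior-predictive checks replay each subject's condition
sequences through the model at MAP parameters and compare go-rate learning
curves per condition; fidelity is summarized by mean absolute deviation.

## Traditional behavioural analysis

Accuracy per condition (missed = no-go), appetitive bias
`acc(GO_WIN) − acc(NOGO_WIN)` and aversive bias
`acc(NOGO_AVOID) − acc(GO_AVOID)`, a paired t test of congruent vs
incongruent accuracy, and a 2×2 repeated-measures ANOVA (action × valence)
computed from per-subject contrast scores — with 1-df factors each F equals
the squared paired t on the marginal means, which the implementation
asserts on every call. Paired effect sizes report both the change-score-SD
and the pooled-SD convention, because clinical reports frequently leave the
convention implicit and the two can differ severalfold when pre/post scores
are highly correlated.

## Symptom-trajectory model

Weekly IDS-SR totals are modelled (REML linear mixed model, random
per-subject intercepts, Wald tests) as
`ids ~ 1 + step3 + step7 + Δπ⁺·step3 + Δπ⁻·step7`, where step3/step7 are
indicators of weeks ≥ 4 and ≥ 7 — the ends of the appetitive and aversive
therapy phases under the default timeline (configurable). Steps, not ramps,
encode "improvement from the phase to the end". Random effects are limited
to intercepts: with ≤ 10 observations per subject, random slopes are not
estimable. Zero-variance design columns are dropped and flagged; a
degenerate (zero residual) fit falls back to OLS with subject dummies for
exact point estimates. Null variants substitute any per-subject change
score (e.g. learning-rate or noise changes) into the same design.

A calibration caveat, measured in the test suite: when outcomes contain a
true parameter-change effect and the regressor is an unrelated (permuted)
change score, Wald intervals cover zero in ~83% rather than 95% of
replicates — the unmodelled subject-level effect is structure that random
intercepts cannot absorb. This is a property of the intercepts-only design,
kept deliberately, and worth remembering when reading null-variant p-values.

## Diary analyses

From each completed activity the pipeline derives prediction errors
`δ_R = r − R_pre`, immediate prediction changes `ΔR¹ = R_post1 − R_pre`,
long-horizon changes `ΔR² = R_pre(next planning of the same activity) −
R_pre` (attached to the earlier planning, whose δ is the natural
regressor; each planning pairs at most once), and a strict next-day
repetition flag (same activity identifier on day+1). Punishment streams are
analogous.

Updating regressions are linear mixed models with random per-subject
intercepts and slopes. The fitting chain tries the correlated
intercept+slope structure under three optimizers, then an uncorrelated
variance-components structure, and only then drops to intercept-only
(flagged) — intercept-only standard errors ignore between-subject slope
variance and are a last resort. Repetition is modelled with a GEE logistic
regression (exchangeable working correlation, cluster-robust standard
errors): with ~12 clusters this stays calibrated where subject-specific
logistic mixed fits are unstable — a variational Bayes mixed logistic fit
was measured at a ~45% false-positive rate under a null generator and
rejected. Item-moderation models add a between-subject item change (or its
baseline score, as a control) and its interaction with δ; interaction
p-values are Bonferroni-corrected for the two anhedonia items (19: general
interest; 21: capacity for pleasure). Item changes are coded end − start,
so improvements are negative. All diary analyses are equivariant to affine
changes of the (unspecified) rating scale, which the tests assert; the
default scale is 0–10 integers.

## Synthetic-data generators

**Task cohorts** draw subject parameters from a Gaussian prior on the
transformed scale; defaults α = 0.2, β = 3, b = 0.3, ξ = 0.05, π⁺ = π⁻ =
0.5 pre-change rising to 1.0 post-change, SD 0.5 per transformed parameter.
The generator defaults to the `conventional` outcome rule: only under that
coding do win stimuli accumulate positive Pavlovian value, producing the
canonical behavioural signature — congruent > incongruent accuracy with
no-go-to-win worst at baseline. (Under the `paper_text` coding, losses for
wrong go responses at win stimuli drive V negative and the conflict largely
vanishes; the rule is still available for sensitivity analyses.) Note the
ordering is a baseline phenomenon: because the default aversive weight
*rises* after its therapy phase, go-to-avoid degrades in later
administrations.

**Diary cohorts** give each agent latent reward/punishment expectations per
activity (14 activities across the seven activity categories, initialized
mid-scale), updated as `R_a ← R_a + ρ(r − R_a)` with per-subject update
rate ρ ~ N(0.7, 0.1) — the regime of the headline updating slope — where r
is experienced around a fixed latent activity value (noise SD 1.5).
Reported ratings are rounded, clipped, noisy readings (SD 0.25) of the
latent expectations. Next-day choice is a softmax over R, or a stay/switch
rule with stay probability logistic in recent reinforcement for
repetition-analysis ground truth. An optional coupling makes ρ depend
linearly on a per-subject item-change score for moderation ground truth.
Because predictor and outcome share the reporting noise on R_pre, the
updating slope is mildly biased upward (~+0.01 at default settings) — a
feature of the measurement design itself, not of the estimator.

**Symptom cohorts** follow the step + parameter-change design exactly, with
default weights (−5, −4, −2, −2), residual SD 2, intercepts ~ N(34.5, 6²),
and parameter changes ~ N(0.5, 0.707²) unless supplied from a task cohort's
truth. Scores are clipped to the 0–84 instrument range.

What the generators deliberately do **not** emulate: reaction-time
dynamics (RTs are i.i.d. lognormal), dropout and missing diary days
(available as an option, default 0), within-session fatigue, activity
categories with distinct semantics, and item-level measurement models for
the symptom items. Passing recovery tests therefore demonstrates estimator
correctness under the stated generative assumptions, not robustness to
every feature of real clinical data.

## Problem sizes and numerical settings

Recovery studies run at the study scale — 12 subjects × 5 administrations ×
240 trials; 56 diary days; 10 weekly symptom scores — with 10 replicate
cohorts for parameter/model recovery and 50 replicates for the regression
recoveries. The acceptance script uses 3 task cohorts and 20 regression
replicates, sizes chosen to give stable summary statistics. MAP
optimization uses convergence tolerance 1e-6 on the objective with 10
random restarts at the first EM iteration and warm starts plus 2 restarts
thereafter. Likelihood kernels are JIT-compiled; choice probabilities are
floored at 1e-300 before taking logs so ξ = 0 models remain finite.

## Known limitations

- The iBIC marginal estimator samples from the fitted prior; with 8-d
  parameter spaces the estimate is noticeably noisy and downward-biased,
  affecting all models similarly. Rankings at the observed ΔiBIC scales
  (tens to hundreds of nats) are robust; small ΔiBIC values are not
  interpretable.
- ξ (lapse) is weakly identified at small trial counts and its recovery is
  not asserted.
- Wald inference throughout; no small-sample degrees-of-freedom
  corrections. At 12 subjects, p-values near threshold should be read
  accordingly.
- The EM prior is diagonal; parameter correlations (e.g. between b and π⁺)
  are absorbed into subject-level posteriors but not modelled at the group
  level.
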