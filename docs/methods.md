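# Methods

## Setting and estimand

`trialbench` estimates the effect of a binary *point* treatment given once at
baseline (the motivating application is thrombus aspiration during primary
PCI for ST-elevation myocardial infarction) from a registry table with one
row per patient: baseline covariates L, treatment received A ∈ {0, 1}, and
event times for death and myocardial infarction on a discrete follow-up
grid. Because a registry records the treatment actually received rather than
an assignment, the estimand is the observational analogue of the
per-protocol effect: the contrast of population risks under "everyone
receives a = 1" versus "everyone receives a = 0", identified under
exchangeability given L, positivity, and consistency. Patients are assigned
to the strategy their baseline data were compatible with; follow-up starts
the day after the procedure, so a death on the procedure day is an
eligibility exclusion, not an interval-1 event.

## Discrete-time hazard model

Follow-up is divided into K intervals (default: months; K = 12 or 36).
The cohort is expanded into person-period rows and a pooled logistic
regression is fitted to the per-interval event indicator:

    logit h_k(a, L) = f(k) + a·β + a·g(k) + L'γ

where f(k) is a flexible time-varying intercept and a·g(k) are
treatment-by-time product terms on the same basis. Because per-interval
hazards are small, the fitted probabilities approximate discrete-time
hazards and the model plays the role a Cox model would in continuous time,
while yielding absolute risks directly.

**Time basis.** Three forms are available: per-interval indicators
(saturated), polynomials in k/K, and truncated-power cubic splines with
user knots. The estimator-class default is the saturated indicator basis:
it nests every alternative and makes the covariate-free model reproduce the
Kaplan–Meier complement exactly, which the test suite exploits as an oracle.
The configuration/CLI default is the cubic polynomial: with product terms on
a saturated basis the MLE only exists when every arm × interval cell
contains an event, which realistic cohorts do not satisfy at K = 36. The
product terms drop the first basis column to avoid collinearity with the
treatment main effect.

**Competing risks.** Death is terminal. For MI the default coding targets
the *total effect*: a patient who dies MI-free keeps contributing event-free
rows through the horizon, so the cumulative quantity is P(MI by k) with
death treated as a non-event rather than as censoring. A censor-at-death
coding is available as a sensitivity analysis. Within an interval MI is
evaluated before death, so an MI in the death interval counts under both
codings; this convention is mirrored by the synthetic generator and the
truth oracle.

**Covariate handling.** Fully observed continuous covariates enter linearly;
a continuous covariate with any missing values is quartile-binned with an
explicit "Missing" level (missing-indicator analysis), matching how registry
baseline tables report missingness as its own category. Categorical
covariates are dummy-coded with "Missing" as its own level when present.
A complete-case switch drops patients with any missing adjustment covariate
instead. A categorical level seen at prediction but not at fit time is an
error, never a silent remap to the reference level — silent remapping would
corrupt the standardization.

**Fitting.** Deterministic Newton/IRLS with log-likelihood step-halving,
convergence when the largest coefficient step falls below 1e-10, at most
100 iterations. The solver is in-package because the bootstrap refits the
model hundreds to thousands of times and per-call overhead dominates
otherwise; unit tests pin its coefficients against statsmodels and against a
direct numeric search of the likelihood. Separation and non-convergence are
flagged on the fitted object; standardization refuses a non-converged model,
and the bootstrap skips such resamples (more than 10% skipped is a hard
error).

## g-formula standardization

For each strategy a, every subject's covariate vector is pushed through the
fitted model to get hazards h_k(a, L_i), the per-subject cumulative risk
1 − Π_{j≤k}(1 − h_j(a, L_i)) is formed, and the standardized curve is the
average over the *entire* analysis population regardless of treatment
received. Risks are contrasted as differences (reported in percentage
points, one decimal) and ratios (two decimals). An arm-specific option fits
a separate outcome model within each arm — allowing all treatment-covariate
interactions — and standardizes each over the full cohort.

## Inverse probability weighting

The IPW alternative fits a logistic propensity model Pr[A = 1 | L] on the
same adjustment set, forms stabilized weights sw = Pr[A = a]/Pr[A = a | L]
(mean ≈ 1; untruncated by default, symmetric percentile truncation available
and logged), and fits a weighted pooled logistic model with treatment and
time terms only; the per-arm plug-in curve is then already marginal.
Weighted standardized mean differences document the balance the weights
achieve. Fitted propensities of exactly 0 or 1 raise a positivity error.

## Bootstrap inference

Nonparametric percentile bootstrap with B = 200 resamples by default:
subjects (never person-period rows) are resampled with replacement, the
*entire* pipeline — model fit plus standardization — is re-run per resample,
and the 95% interval is the pair of order statistics at ranks ⌈0.025·B⌉ and
⌈0.975·B⌉. Eligibility is not re-run inside resamples; the resampling unit
is the analyzed cohort, matching the stated analysis population. One run
can bootstrap many statistics jointly so all CIs come from the same
resamples. Resample fits may be warm-started at the full-data MLE, which
changes nothing statistically (the MLE is unique) and roughly halves Newton
iterations.

## Benchmarking rule

The emulation's 1-year estimates are compared with the index randomized
trial's published results, typed in by the user as a small JSON file.
Per outcome the report records CI overlap, null-compatibility of each study,
and a decision-concordance verdict: concordant if both CIs include the null,
or both exclude it on the same side. Benchmarking succeeds only if every
benchmarked outcome is concordant. A published hazard ratio is accepted as
the trial-side ratio but flagged as an estimand-scale caveat, since the
emulation reports risk ratios. No formal test of trial-vs-emulation
difference is attempted; the comparison is deliberately informal.

## Subgroup and period stratification

The full pipeline (fit, standardize, bootstrap) is re-run within strata of
sex, age (<65/≥65), diabetes, previous PCI, previous MI, and calendar
period. Period stratification probes whether the confounding structure
changed when practice changed (e.g. after a null trial, when the treatment
is reserved for selected anatomy): if pre- and post-period estimates agree
within sampling error, pooling both periods for benchmarking is defensible.
Strata in which an arm has no events are flagged unstable rather than
silently dropped.

## Synthetic registry generator

The generator emulates the *structure* of a nationwide PCI registry, not any
actual covariate distribution. Baseline covariates come from a Gaussian
copula over specified marginals (binary, categorical, Normal), giving
mixed-type tables with a chosen correlation block. Treatment is Bernoulli
with logit linear in covariates (continuous covariates centered at their
marginal mean); a binary calendar period can carry its own assignment
model, emulating a practice change. Death and MI are simulated
interval-by-interval from logistic hazards with per-interval baseline
schedules; death is terminal and MI is drawn before death within an
interval. Missingness is MCAR per covariate, applied to the *recorded*
values only, so complete-case and missing-indicator analyses are both
consistent for testing.

Default reference conditions (`default_config`): n = 8,000, 36 monthly
intervals, ~19% treated; declining hazard schedules calibrated once so that
the untreated arm's risks are ≈7.3%/12.4% (death, 1y/3y) and ≈4.1%/6.9%
(MI), typical of an all-comers post-PCI population; a *null* true treatment
effect on both outcomes; confounding through age (older → less often
treated, higher risk) and total occlusion (more often treated, higher risk)
with age dominating, so the unadjusted comparison is biased protective by
roughly −1.5 percentage points at one year; 45% of subjects in the "post"
period with halved uptake and a stronger occlusion criterion; MCAR
missingness in BMI (24%), smoking (8%) and vitals (6%).

**Truth oracle.** The standardized risk under "everyone receives a" is
computed exactly when all covariates are discrete and independent (stratum
enumeration) and otherwise by Monte Carlo over the covariate distribution
with a reported standard error; the event process is always handled
analytically given covariates: death risk is 1 − Π(1 − h_d,k) and MI truth
accumulates h_m,k over the joint MI-free-and-alive survivor function.
Parameter-recovery tests compare estimates against this oracle, never
against another estimator.

What passing tests on this generator do *not* show: robustness to informative
missingness (the generator is MCAR), to unmeasured confounding, to
measurement error in treatment or outcomes, or to model misspecification
beyond the time-basis misfit deliberately present (the true baseline hazard
is exponential-decay-plus-floor, which no polynomial matches exactly).

## Problem sizes

Simulation-based checks use sizes chosen to make Monte-Carlo error small
relative to the effects probed: parameter recovery uses 200 replicates at
n = 2,000; bootstrap coverage uses 100 replicates at n = 1,500, K = 6,
B = 100; the acceptance script runs one full emulation at n = 6,000 with
B = 200 and 36 monthly intervals. These are the package's reference sizes;
all scale linearly in n, K and B.

## Known limitations

- Point treatments only: no sustained strategies, no time-varying
  treatment or confounders, hence no need for the longitudinal g-formula.
- No doubly-robust estimator (AIPW/TMLE); g-formula and IPW only.
- The percentile bootstrap can undercover when B is very small or the
  statistic is strongly skewed; B = 200 with ~500+ events behaves well in
  the coverage study.
- The benchmark compares a risk ratio with a published hazard ratio when
  that is all the trial reports; the report flags this scale caveat rather
  than converting, since conversion would need the trial's survival curves.
- Registry-specific outcome-definition variants (e.g. readmission-gap rules
  for MI) are out of scope; the config exposes coding and eligibility hooks
  instead.
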