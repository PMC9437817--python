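# trialbench

Target-trial emulation for point treatments, with benchmarking against an
index randomized trial.

## The problem

Randomized trials cannot answer every effectiveness question: follow-up is
often short, and underrepresented subgroups are too small. Registries can —
but registry estimates may be confounded, because treatment under routine
care depends on patient characteristics. One way to earn trust in a registry
analysis is to *benchmark* it first: emulate a target trial that asks the
same question as a completed randomized trial, check that the emulation
reproduces the trial's result, and only then use the registry to extend
follow-up or estimate subgroup effects the trial could not.

`trialbench` implements that workflow for a binary point treatment (the
motivating setting is thrombus aspiration during primary PCI for STEMI,
with death and myocardial infarction as outcomes):

- eligibility screening with a selection flowchart, per-protocol strategy
  assignment ("the strategy the patient's data were compatible with"),
  baseline tables and standardized mean differences;
- discrete-time pooled logistic hazard models on person-period data, with a
  flexible time-varying intercept and treatment-by-time product terms;
- g-formula standardization over the full eligible cohort, and a stabilized
  inverse-probability-weighting alternative;
- total-effect handling of the competing risk of death for the nonfatal
  outcome (death is a non-event, not a censoring event), with
  censor-at-death as a sensitivity;
- subject-level nonparametric percentile bootstrap (B = 200) for all CIs;
- an explicit decision-concordance benchmark against the index trial's
  published estimates;
- subgroup and calendar-period stratified analyses;
- a synthetic registry generator with a known-truth oracle, so every stage
  is testable without access to confidential registry data.

## The model

Follow-up is split into K monthly intervals and the cohort is expanded to
person-period rows. The per-interval event indicator follows a pooled
logistic model

    logit h_k(a, L) = f(k) + a·β + a·g(k) + L'γ,

whose fitted probabilities approximate discrete-time hazards h_k. The
standardized risk under strategy a is the g-formula plug-in

    R_k(a) = (1/n) Σ_i [ 1 − Π_{j≤k} (1 − h_j(a, L_i)) ],

averaged over *all* eligible patients regardless of the treatment they
actually received. Effects are reported as risk differences RD = R(1) − R(0)
in percentage points and risk ratios RR = R(1)/R(0) at 1- and 3-year
horizons. The IPW alternative reweights patients by
sw = Pr[A = a]/Pr[A = a | L] and fits the weighted hazard model with
treatment and time terms only. See `docs/methods.md` for assumptions,
numerical choices and limitations.

## Worked example

```python
import trialbench as tb

# synthetic registry under the package's reference conditions:
# confounded treatment (~19% treated), null true effect on both outcomes
config = tb.default_config(n_subjects=6000, seed=1)
registry = tb.generate_registry(config)
eligible, flowchart = tb.apply_eligibility(registry, tb.standard_criteria(min_age=18))
cohort = tb.assign_strategy(eligible)

adjust = ["age", "female", "diabetes", "prev_mi", "prev_pci",
          "total_occlusion", "smoking", "bmi", "heart_rate", "sbp"]
est = tb.GFormulaRiskEstimator("death", horizon=12, adjustment=adjust,
                               time_form="poly").fit(cohort)
print(est.effect(12).formatted())

km1 = tb.kaplan_meier(cohort, 1, "death", 12)
km0 = tb.kaplan_meier(cohort, 0, "death", 12)
print("unadjusted KM RD (pp):", round(100 * (km1.risk_at(12) - km0.risk_at(12)), 2))
```

Output:

```
{'outcome': 'death', 'horizon': 12, 'estimator': 'gformula', 'label': 'main',
 'risk1_pct': 5.1, 'risk0_pct': 6.8, 'rd_pp': -1.7, 'rr': 0.75}
unadjusted KM RD (pp): -2.89
```

Reading the numbers: the generating law has a *null* treatment effect, but
treated patients are younger and therefore lower-risk, so the naive
Kaplan–Meier comparison is biased to −2.9 percentage points. Covariate
adjustment with g-formula standardization moves the estimate to −1.7, and
the bootstrap 95% CI (computed by the acceptance script for this same seed)
spans roughly ±1.4 around it — this particular draw sits about two sampling
standard deviations from the truth of 0; across seeds the estimator is
unbiased, which the test suite checks over 200 replicates.

The same pipeline is available as a CLI:

```bash
trialbench generate -c generation.yaml -o data/
trialbench emulate  -c analysis.yaml   -o results/
trialbench benchmark --effects results/effects.json --trial index_trial.json -o bench.json
trialbench subgroups -c analysis.yaml  -o results/subgroups/
```

where `analysis.yaml` names the registry CSV, outcomes, horizons,
adjustment set, estimators (`gformula`, `ipw`), bootstrap size and seed, and
sensitivity toggles (complete-case, age/sex-only adjustment,
censor-at-death, arm-specific models). Every run writes a manifest (config
hash, seed, version) sufficient to reproduce the bundle bit for bit.

## Layout

```
src/trialbench/
  simulate.py     synthetic registry generator + true-risk oracle
  cohort.py       eligibility, strategy assignment, balance, Kaplan-Meier
  hazard.py       person-period expansion, pooled logistic hazard model
  estimators.py   GFormulaRiskEstimator, IPWRiskEstimator, weights
  inference.py    percentile bootstrap, benchmark report, subgroups
  report.py       end-to-end runs, report bundles, survival plots
  cli.py          generate / emulate / benchmark / subgroups commands
docs/methods.md   model, assumptions, defaults, limitations
```
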