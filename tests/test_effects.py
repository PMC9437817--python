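"""g-formula standardization, IPW, propensity scores and effect contrasts."""

import numpy as np
import pytest
from scipy.special import expit

import trialbench as tb
from trialbench.errors import ModelConvergenceError, PositivityError
from trialbench.estimators import _cumulative_risk
from trialbench.hazard import expand_person_periods
from trialbench.results import RiskCurve

from conftest import make_cohort, two_binary_config


class TestStandardizedCurve:
    def test_zero_hazards_give_zero_cumulative_risk(self):
        assert np.all(_cumulative_risk(np.zeros((3, 5))) == 0.0)

    def test_three_way_oracle_agreement_exact(self, small_cohort):
        """Covariate-free standardized curve == plug-in curve == KM complement
        on saturated-time, no-censoring data, to 1e-12."""
        K = 8
        pp = expand_person_periods(small_cohort, "death", K)
        model = tb.PooledLogisticHazard().fit(pp)
        for arm in (0, 1):
            gform = tb.standardized_risk_curve(model, small_cohort, arm, K)
            plug_in = 1.0 - np.cumprod(1.0 - model.predict_hazard_matrix(small_cohort.iloc[:1], arm, K)[0])
            km = tb.kaplan_meier(small_cohort, arm, "death", K)
            assert np.abs(gform.risks - plug_in).max() < 1e-12
            assert np.abs(gform.risks - km.risks).max() < 1e-12

    def test_recovers_true_standardized_risk(self):
        cfg = two_binary_config(n=10_000, seed=21, treatment_effect=-0.25)
        coh = tb.assign_strategy(tb.generate_registry(cfg))
        est = tb.GFormulaRiskEstimator("death", 12, adjustment=["x1", "x2"]).fit(coh)
        oracle = tb.TrueEffectOracle(cfg)
        for arm in (0, 1):
            r = est.predict_risk(arm).risk_at(12)
            truth = oracle.true_risk(arm, 12)
            n_arm = (coh["treatment"] == arm).sum()
            se = np.sqrt(truth * (1 - truth) / n_arm)
            assert abs(r - truth) < 3 * se

    def test_non_converged_model_is_refused(self, small_cohort):
        pp = expand_person_periods(small_cohort, "death", 6)
        model = tb.PooledLogisticHazard().fit(pp)
        model.converged_ = False
        with pytest.raises(ModelConvergenceError):
            tb.standardized_risk_curve(model, small_cohort, 1, 6)

    def test_complete_case_restricts_standardization_population(self):
        cfg = tb.default_config(1500, seed=2)
        coh = tb.assign_strategy(tb.generate_registry(cfg))
        est = tb.GFormulaRiskEstimator(
            "death", 6, adjustment=["age", "bmi"], complete_case=True, time_form="poly"
        ).fit(coh)
        assert len(est.cohort_) == len(coh.dropna(subset=["age", "bmi"]))

    def test_arm_specific_models_standardize_over_full_cohort(self):
        cfg = two_binary_config(n=6000, seed=31)
        coh = tb.assign_strategy(tb.generate_registry(cfg))
        pooled = tb.GFormulaRiskEstimator("death", 8, adjustment=["x1", "x2"]).fit(coh)
        armwise = tb.GFormulaRiskEstimator(
            "death", 8, adjustment=["x1", "x2"], arm_specific=True
        ).fit(coh)
        assert set(armwise.models_) == {0, 1}
        # same estimand under the null: estimates agree within sampling slack
        assert armwise.effect(8).rd == pytest.approx(pooled.effect(8).rd, abs=1.5)


class TestContrast:
    def test_identical_curves_give_null_effect(self):
        c = RiskCurve(1, np.array([0.01, 0.02]), "gformula", "death")
        c0 = RiskCurve(0, np.array([0.01, 0.02]), "gformula", "death")
        eff = tb.contrast(c, c0, 2)
        assert eff.rd == 0.0 and eff.rr == 1.0

    def test_zero_reference_risk_yields_undefined_ratio_sentinel(self):
        c1 = RiskCurve(1, np.array([0.1]), "gformula")
        c0 = RiskCurve(0, np.array([0.0]), "gformula")
        with pytest.warns(UserWarning, match="undefined"):
            eff = tb.contrast(c1, c0, 1)
        assert not eff.rr_defined and np.isnan(eff.rr)
        assert eff.rd == pytest.approx(10.0)

    def test_mismatched_estimators_refused(self):
        c1 = RiskCurve(1, np.array([0.1]), "gformula")
        c0 = RiskCurve(0, np.array([0.1]), "ipw")
        with pytest.raises(ValueError, match="estimator"):
            tb.contrast(c1, c0, 1)

    def test_monotonicity_enforced_on_every_curve(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            RiskCurve(1, np.array([0.2, 0.1]), "gformula")

    def test_sensitivity_gap_between_full_and_age_sex_adjustment(self):
        # when only x1 ("age") confounds, adjusting for x1 alone removes all
        # bias, so the fully adjusted and x1-adjusted RDs coincide
        cfg = two_binary_config(n=20_000, seed=13)
        cfg.treatment_model.coef = {"x1": 0.9}
        coh = tb.assign_strategy(tb.generate_registry(cfg))
        full = tb.GFormulaRiskEstimator("death", 8, adjustment=["x1", "x2"]).fit(coh)
        agesex = tb.GFormulaRiskEstimator("death", 8, adjustment=["x1"]).fit(coh)
        gap = full.effect(8).rd - agesex.effect(8).rd
        assert abs(gap) < 0.4  # percentage points, sampling slack only


class TestPropensityAndWeights:
    def test_unconfounded_treatment_gives_flat_propensity(self):
        cfg = two_binary_config(n=5000, seed=17, confounded=False)
        coh = tb.assign_strategy(tb.generate_registry(cfg))
        model, ps = tb.fit_propensity(coh, ["x1", "x2"])
        assert np.abs(ps - coh["treatment"].mean()).max() < 0.05

    def test_covariate_free_propensity_is_arm_share(self):
        coh = make_cohort([None] * 40, [None] * 40, [1] * 10 + [0] * 30)
        _, ps = tb.fit_propensity(coh, [])
        assert ps == pytest.approx(np.full(40, 0.25), abs=1e-9)

    def test_predictions_match_hand_computed_inverse_logit(self, small_cohort):
        model, ps = tb.fit_propensity(small_cohort, ["x1", "x2"])
        c = model.coef
        for i in range(3):
            lp = (
                c["intercept"]
                + c["x1"] * small_cohort.iloc[i]["x1"]
                + c["x2"] * small_cohort.iloc[i]["x2"]
            )
            assert ps[i] == pytest.approx(expit(lp), abs=1e-12)

    def test_stabilized_weights_are_one_under_flat_propensity(self):
        coh = make_cohort([None] * 20, [None] * 20, [1] * 5 + [0] * 15)
        ws = tb.stabilized_weights(np.full(20, 0.25), coh)
        assert ws.weights == pytest.approx(np.ones(20), abs=1e-12)
        assert ws.check_mean()

    def test_weight_mean_near_one_on_confounded_cohort(self):
        cfg = two_binary_config(n=10_000, seed=19)
        coh = tb.assign_strategy(tb.generate_registry(cfg))
        _, ps = tb.fit_propensity(coh, ["x1", "x2"])
        ws = tb.stabilized_weights(ps, coh)
        assert abs(ws.mean() - 1.0) < 0.05

    def test_positivity_violation_lists_subjects(self):
        coh = make_cohort([None] * 3, [None] * 3, [1, 0, 1])
        with pytest.raises(PositivityError, match="1"):
            tb.stabilized_weights(np.array([0.0, 0.5, 0.9]), coh)

    def test_truncation_clips_extremes(self):
        coh = make_cohort([None] * 100, [None] * 100, [1, 0] * 50)
        rng = np.random.default_rng(1)
        ps = np.clip(rng.beta(0.6, 1.4, 100), 0.01, 0.99)
        raw = tb.stabilized_weights(ps, coh)
        trunc = tb.stabilized_weights(ps, coh, truncation=(5, 95))
        assert trunc.weights.max() <= raw.weights.max()
        assert trunc.truncation == (5, 95)


class TestIPW:
    def test_unit_weights_reproduce_unadjusted_plug_in_curve(self, small_cohort):
        ipw = tb.IPWRiskEstimator("death", 8, adjustment=[]).fit(small_cohort)
        assert ipw.weights_.weights == pytest.approx(np.ones(len(small_cohort)), abs=1e-9)
        km = tb.kaplan_meier(small_cohort, 1, "death", 8)
        assert np.abs(ipw.predict_risk(1).risks - km.risks).max() < 1e-9

    def test_agrees_with_gformula_under_correct_specification(self):
        cfg = two_binary_config(n=10_000, seed=23)
        coh = tb.assign_strategy(tb.generate_registry(cfg))
        gf = tb.GFormulaRiskEstimator("death", 12, adjustment=["x1", "x2"]).fit(coh)
        ipw = tb.IPWRiskEstimator("death", 12, adjustment=["x1", "x2"]).fit(coh)
        # both consistent under correct specification: RDs close at this n
        assert ipw.effect(12).rd == pytest.approx(gf.effect(12).rd, abs=1.0)

    def test_weighting_restores_covariate_balance(self):
        cfg = two_binary_config(n=10_000, seed=29)
        coh = tb.assign_strategy(tb.generate_registry(cfg))
        ipw = tb.IPWRiskEstimator("death", 6, adjustment=["x1", "x2"]).fit(coh)
        raw = max(abs(tb.standardized_mean_difference(coh, c)) for c in ("x1", "x2"))
        assert raw > 0.1  # confounding is material before weighting
        assert ipw.balance().abs().max() < 0.1
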