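"""Person-period expansion and pooled logistic fitting against independent
oracles (closed forms, brute-force likelihood search, statsmodels)."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit

import trialbench as tb
from trialbench.errors import SingleClassError, UnseenLevelError
from trialbench.hazard import PersonPeriodTable, expand_person_periods, newton_logistic

from conftest import make_cohort, two_binary_config


class TestExpansion:
    def test_event_in_first_interval_gives_single_event_row(self):
        coh = make_cohort([1], [None], [1])
        pp = expand_person_periods(coh, "death", 12)
        assert len(pp) == 1 and pp.data["event"].tolist() == [1]

    def test_event_free_subject_contributes_horizon_rows(self):
        coh = make_cohort([None], [None], [0])
        pp = expand_person_periods(coh, "death", 12)
        assert len(pp) == 12 and pp.data["event"].sum() == 0
        assert pp.data["interval"].tolist() == list(range(1, 13))

    def test_death_without_mi_contributes_event_free_rows_through_horizon(self):
        # total-effect coding: dying MI-free is not a censoring event
        coh = make_cohort([2], [None], [1])
        pp = expand_person_periods(coh, "mi", 4, "total-effect")
        assert len(pp) == 4 and pp.data["event"].sum() == 0

    def test_censor_at_death_stops_rows_at_death(self):
        coh = make_cohort([2], [None], [1])
        pp = expand_person_periods(coh, "mi", 4, "censor-at-death")
        assert len(pp) == 2 and pp.data["event"].sum() == 0

    def test_mi_in_death_interval_still_counts_when_censoring_at_death(self):
        coh = make_cohort([3], [3], [1])
        pp = expand_person_periods(coh, "mi", 6, "censor-at-death")
        assert len(pp) == 3 and pp.data["event"].tolist()[-1] == 1

    def test_event_beyond_horizon_is_event_free(self):
        coh = make_cohort([9], [None], [1])
        pp = expand_person_periods(coh, "death", 6)
        assert len(pp) == 6 and pp.data["event"].sum() == 0

    def test_total_rows_match_per_subject_brute_force(self):
        cfg = two_binary_config(n=50, seed=11, h_death=0.08, h_mi=0.05)
        coh = tb.generate_registry(cfg)
        for outcome, coding in (("death", None), ("mi", "total-effect"), ("mi", "censor-at-death")):
            pp = expand_person_periods(coh, outcome, 10, coding)
            expected = 0
            for _, r in coh.iterrows():
                d = r["death_interval"] if r["death_interval"] is not pd.NA else np.inf
                m = r["mi_interval"] if r["mi_interval"] is not pd.NA else np.inf
                if outcome == "death":
                    expected += min(d, 10)
                elif coding == "total-effect":
                    expected += min(m, 10)
                else:
                    expected += min(m if m <= min(d, 10) else np.inf, d, 10)
            assert len(pp) == expected, (outcome, coding)

    def test_unknown_coding_rejected(self):
        coh = make_cohort([1], [None], [1])
        with pytest.raises(ValueError, match="coding"):
            expand_person_periods(coh, "death", 4, "weird")

    def test_at_most_one_event_row_per_subject(self, small_cohort):
        pp = expand_person_periods(small_cohort, "death", 12)
        assert pp.data.groupby("id")["event"].sum().max() <= 1
        intervals = pp.data.groupby("id")["interval"].agg(["min", "max", "count"])
        assert (intervals["min"] == 1).all()
        assert (intervals["max"] == intervals["count"]).all()  # contiguous 1..m


def _pp_from_events(events, treatment=None, **covs):
    n = len(events)
    df = pd.DataFrame({"interval": np.ones(n, dtype=int), "event": events})
    df["treatment"] = treatment if treatment is not None else np.zeros(n, dtype=int)
    for k, v in covs.items():
        df[k] = v
    return PersonPeriodTable(data=df, outcome="death", horizon=1, coding="terminal")


class TestPooledLogisticFit:
    def test_intercept_only_hazard_is_event_fraction(self):
        pp = _pp_from_events([0, 1] * 25)
        model = tb.PooledLogisticHazard(include_treatment=False).fit(pp)
        assert model.converged_
        assert model.predict_hazard(pp.data) == pytest.approx(np.full(50, 0.5), abs=1e-12)

    def test_saturated_time_hazards_equal_cell_proportions(self, small_cohort):
        pp = expand_person_periods(small_cohort, "death", 8)
        model = tb.PooledLogisticHazard().fit(pp)  # saturated in arm x interval
        for arm in (0, 1):
            H = model.predict_hazard_matrix(small_cohort.iloc[:1], arm, 8)[0]
            sub = pp.data[pp.data["treatment"] == arm]
            observed = sub.groupby("interval")["event"].mean().to_numpy()
            assert H == pytest.approx(observed, abs=1e-10)

    def test_coefficients_match_brute_force_likelihood_search(self):
        # independent oracle: numeric minimization of the negative log-likelihood
        rng = np.random.default_rng(3)
        n = 100
        coh = make_cohort(
            [None] * n, [None] * n, rng.integers(0, 2, n),
            x1=rng.integers(0, 2, n), x2=rng.normal(0, 1, n),
        )
        lp = -1.0 + 0.8 * coh["x1"] + 0.5 * coh["x2"] + 0.3 * coh["treatment"]
        h = expit(lp.to_numpy())
        # two intervals of constant per-subject hazard
        draws = rng.random((n, 2)) < h[:, None]
        death = [int(np.argmax(d)) + 1 if d.any() else None for d in draws]
        coh["death_interval"] = pd.array(death, dtype="Int64")
        pp = expand_person_periods(coh, "death", 2)
        model = tb.PooledLogisticHazard(adjustment=["x1", "x2"], products=False).fit(pp)

        d = pp.data
        X = np.column_stack([
            (d["interval"] == 1).astype(float), (d["interval"] == 2).astype(float),
            d["treatment"].astype(float), d["x1"].astype(float), d["x2"].astype(float),
        ])
        y = d["event"].to_numpy(float)

        def nll(beta):
            eta = X @ beta
            return -np.sum(y * eta - np.logaddexp(0.0, eta))

        res = minimize(nll, np.zeros(5), method="BFGS", options={"gtol": 1e-12, "maxiter": 500})
        assert model.coef_.to_numpy() == pytest.approx(res.x, abs=1e-4)

    def test_matches_statsmodels_newton(self, small_cohort):
        pp = expand_person_periods(small_cohort, "death", 6)
        model = tb.PooledLogisticHazard(adjustment=["x1", "x2"]).fit(pp)
        d = pp.data
        tb_ = np.equal.outer(d["interval"].to_numpy(), np.arange(1, 7)).astype(float)
        a = d["treatment"].to_numpy(float)
        X = np.column_stack([tb_, a, tb_[:, 1:] * a[:, None],
                             d["x1"].astype(float), d["x2"].astype(float)])
        res = sm.Logit(d["event"].to_numpy(float), X).fit(
            method="newton", tol=1e-10, maxiter=200, disp=0
        )
        assert model.coef_.to_numpy() == pytest.approx(res.params, abs=1e-8)
        assert model.loglik_ == pytest.approx(res.llf, abs=1e-8)

    def test_loglik_no_worse_than_null_coefficients(self, small_cohort):
        pp = expand_person_periods(small_cohort, "death", 6)
        model = tb.PooledLogisticHazard(adjustment=["x1"]).fit(pp)
        assert model.loglik_ >= len(pp.data) * np.log(0.5)

    def test_row_permutation_leaves_coefficients_unchanged(self, small_cohort):
        pp = expand_person_periods(small_cohort, "death", 6)
        model = tb.PooledLogisticHazard(adjustment=["x1"]).fit(pp)
        shuffled = PersonPeriodTable(
            pp.data.sample(frac=1.0, random_state=1).reset_index(drop=True),
            pp.outcome, pp.horizon, pp.coding,
        )
        model2 = tb.PooledLogisticHazard(adjustment=["x1"]).fit(shuffled)
        assert model2.coef_.to_numpy() == pytest.approx(model.coef_.to_numpy(), abs=1e-10)

    def test_single_outcome_class_rejected(self):
        pp = _pp_from_events([0] * 20)
        with pytest.raises(SingleClassError):
            tb.PooledLogisticHazard(include_treatment=False).fit(pp)

    def test_complete_separation_flagged_not_raised(self):
        pp = _pp_from_events([0] * 20 + [1] * 20, x=np.r_[np.zeros(20), np.ones(20)])
        model = tb.PooledLogisticHazard(include_treatment=False, adjustment=["x"]).fit(pp)
        assert not model.converged_
        assert model.separation_message_


class TestPrediction:
    def test_covariate_free_hazards_identical_across_subjects(self, small_cohort):
        pp = expand_person_periods(small_cohort, "death", 6)
        model = tb.PooledLogisticHazard().fit(pp)
        H = model.predict_hazard_matrix(small_cohort, 1, 6)
        assert np.ptp(H, axis=0) == pytest.approx(np.zeros(6), abs=1e-15)

    def test_null_treatment_coefficients_give_equal_arms(self, small_cohort):
        pp = expand_person_periods(small_cohort, "death", 6)
        model = tb.PooledLogisticHazard(adjustment=["x1"], products=False).fit(pp)
        model.coef_["treatment"] = 0.0
        H0 = model.predict_hazard_matrix(small_cohort, 0, 6)
        H1 = model.predict_hazard_matrix(small_cohort, 1, 6)
        assert H0 == pytest.approx(H1, abs=1e-15)

    def test_matches_hand_computed_inverse_logit(self, small_cohort):
        pp = expand_person_periods(small_cohort, "death", 6)
        model = tb.PooledLogisticHazard(adjustment=["x1", "x2"], products=False).fit(pp)
        c = model.coef_
        three = small_cohort.iloc[:3]
        H = model.predict_hazard_matrix(three, 1, 6)
        for i in range(3):
            for k in range(1, 7):
                lp = (
                    c[f"t[{k}]"] + c["treatment"]
                    + c["x1"] * three.iloc[i]["x1"] + c["x2"] * three.iloc[i]["x2"]
                )
                assert H[i, k - 1] == pytest.approx(expit(lp), abs=1e-12)

    def test_unseen_categorical_level_is_an_error(self):
        n = 60
        rng = np.random.default_rng(0)
        coh = make_cohort(
            [1 if r < 0.3 else (2 if r < 0.6 else None) for r in rng.random(n)],
            [None] * n,
            rng.integers(0, 2, n), grp=np.r_[["a"] * 30, ["b"] * 30],
        )
        pp = expand_person_periods(coh, "death", 2)
        model = tb.PooledLogisticHazard(adjustment=["grp"]).fit(pp)
        other = coh.assign(grp="c")
        with pytest.raises(UnseenLevelError, match="'c'"):
            model.predict_hazard_matrix(other, 1, 2)


def test_warm_start_reaches_identical_mle(small_cohort):
    # the MLE is unique: warm-starting at another fit's solution must not
    # change the coefficients, only the iteration count
    pp = expand_person_periods(small_cohort, "death", 6)
    cold = tb.PooledLogisticHazard(adjustment=["x1", "x2"]).fit(pp)
    warm = tb.PooledLogisticHazard(
        adjustment=["x1", "x2"], warm_start=cold.coef_.to_numpy() + 0.05
    ).fit(pp)
    assert warm.converged_
    assert warm.coef_.to_numpy() == pytest.approx(cold.coef_.to_numpy(), abs=1e-9)


def test_newton_solver_agrees_with_statsmodels_weighted():
    rng = np.random.default_rng(5)
    X = np.column_stack([np.ones(500), rng.normal(size=(500, 2))])
    y = (rng.random(500) < expit(X @ np.array([-0.5, 1.0, -0.7]))).astype(float)
    w = rng.uniform(0.5, 2.0, 500)
    beta, ll, conv, _ = newton_logistic(X, y, sample_weight=w)
    res = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w).fit(tol=1e-12)
    assert conv
    assert beta == pytest.approx(np.asarray(res.params), abs=1e-8)


def test_coefficients_serialize_to_json(small_cohort):
    pp = expand_person_periods(small_cohort, "death", 4)
    model = tb.PooledLogisticHazard(adjustment=["x1"]).fit(pp)
    import json as _json
    payload = _json.loads(model.coefficients_json())
    assert payload["converged"] is True
    assert payload["coefficients"]["x1"] == pytest.approx(model.coef_["x1"])
    assert payload["outcome"] == "death" and payload["horizon"] == 4
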