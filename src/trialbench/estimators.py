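"""Standardized (g-formula) and inverse-probability-weighted risk estimation.

The per-protocol analysis fits one pooled logistic hazard model on the
person-period data and then standardizes: for each strategy a, every
eligible subject's covariate vector is pushed through the model to get
per-interval hazards h_k(a, L_i), the per-subject cumulative risk
1 - prod_{j<=k} (1 - h_j(a, L_i)) is formed, and the curve is the average
over the entire analysis population regardless of the treatment actually
received.  The IPW alternative reweights subjects by stabilized inverse
probability of treatment weights and fits a weighted hazard model with
treatment and time terms only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cohort import standardized_mean_difference
from .errors import ModelConvergenceError, PositivityError, SingleClassError
from .hazard import (
    PersonPeriodTable,
    PooledLogisticHazard,
    _Design,
    expand_person_periods,
    newton_logistic,
)
from .results import EffectEstimate, RiskCurve, contrast

__all__ = [
    "GFormulaRiskEstimator",
    "IPWRiskEstimator",
    "PropensityModel",
    "WeightSet",
    "standardized_risk_curve",
    "fit_propensity",
    "stabilized_weights",
    "ipw_risk_curves",
]


def _cumulative_risk(hazards: np.ndarray) -> np.ndarray:
    """Per-subject cumulative risk from an (n, K) hazard matrix."""
    return 1.0 - np.cumprod(1.0 - hazards, axis=1)


def standardized_risk_curve(
    model: PooledLogisticHazard, cohort: pd.DataFrame, strategy: int, K: int
) -> RiskCurve:
    """g-formula curve: average per-subject cumulative risk under ``strategy``.

    The standardization population is the full cohort passed in (both arms).
    Refuses a non-converged model.
    """
    if not getattr(model, "converged_", False):
        raise ModelConvergenceError(
            getattr(model, "separation_message_", None) or "hazard model did not converge"
        )
    H = model.predict_hazard_matrix(cohort, strategy, K)
    risks = _cumulative_risk(H).mean(axis=0)
    return RiskCurve(strategy=strategy, risks=risks, estimator="gformula", outcome=model.outcome_)


class GFormulaRiskEstimator(BaseEstimator):
    """Pooled-logistic g-formula estimator for a point treatment.

    Parameters
    ----------
    outcome : {"death", "mi"}
    horizon : int
        Number of discrete follow-up intervals (e.g. 12 or 36 months).
    coding : str, optional
        Competing-risk coding; defaults to "terminal" for death and
        "total-effect" for MI, with "censor-at-death" as an MI sensitivity.
    adjustment : sequence of str
        Baseline covariates in the outcome model.
    time_form, degree, knots, products
        Time-varying intercept shape, forwarded to the hazard model.
    arm_specific : bool
        Fit a separate outcome model within each treatment arm (all
        treatment-covariate interactions) and standardize each over the full
        cohort.
    complete_case : bool
        Drop subjects with any missing adjustment covariate instead of using
        missing-indicator categories.

    Attributes
    ----------
    models_ : dict
        Fitted :class:`PooledLogisticHazard` per arm (key "pooled" unless
        arm-specific).
    risk_curves_ : dict[int, RiskCurve]
    cohort_ : pandas.DataFrame
        The standardization population actually used.
    """

    def __init__(
        self,
        outcome: str = "death",
        horizon: int = 12,
        coding: str | None = None,
        adjustment: Sequence[str] = (),
        time_form: str = "indicator",
        degree: int = 3,
        knots: Sequence[float] | None = None,
        products: bool = True,
        arm_specific: bool = False,
        complete_case: bool = False,
        tol: float = 1e-10,
        maxiter: int = 100,
        warm_start: np.ndarray | None = None,
    ) -> None:
        self.outcome = outcome
        self.horizon = horizon
        self.coding = coding
        self.adjustment = adjustment
        self.time_form = time_form
        self.degree = degree
        self.knots = knots
        self.products = products
        self.arm_specific = arm_specific
        self.complete_case = complete_case
        self.tol = tol
        self.maxiter = maxiter
        self.warm_start = warm_start

    def _hazard_params(self) -> dict:
        return dict(
            time_form=self.time_form,
            degree=self.degree,
            knots=self.knots,
            adjustment=list(self.adjustment),
            tol=self.tol,
            maxiter=self.maxiter,
        )

    def fit(self, cohort: pd.DataFrame) -> "GFormulaRiskEstimator":
        data = cohort
        if self.complete_case and self.adjustment:
            data = cohort.dropna(subset=list(self.adjustment))
        if len(data) == 0:
            raise ValueError("empty cohort after complete-case restriction")
        if data["treatment"].nunique() < 2:
            raise SingleClassError("cohort contains a single treatment arm")
        self.cohort_ = data.reset_index(drop=True)
        pp = expand_person_periods(self.cohort_, self.outcome, self.horizon, self.coding)
        self.coding_ = pp.coding
        self.models_ = {}
        if self.arm_specific:
            for arm in (0, 1):
                sub = PersonPeriodTable(
                    data=pp.data[pp.data["treatment"] == arm].reset_index(drop=True),
                    outcome=pp.outcome, horizon=pp.horizon, coding=pp.coding,
                )
                model = PooledLogisticHazard(
                    include_treatment=False, products=False, **self._hazard_params()
                ).fit(sub)
                self.models_[arm] = model
        else:
            model = PooledLogisticHazard(
                include_treatment=True, products=self.products,
                warm_start=self.warm_start, **self._hazard_params()
            ).fit(pp)
            self.models_["pooled"] = model
        self.risk_curves_ = {
            a: self._curve(a) for a in (0, 1)
        }
        return self

    def _curve(self, strategy: int) -> RiskCurve:
        model = self.models_[strategy] if self.arm_specific else self.models_["pooled"]
        curve = standardized_risk_curve(model, self.cohort_, strategy, self.horizon)
        curve.strategy = strategy
        return curve

    def predict_risk(self, strategy: int) -> RiskCurve:
        if not hasattr(self, "risk_curves_"):
            raise RuntimeError("estimator is not fitted")
        return self.risk_curves_[int(strategy)]

    def effect(self, horizon: int | None = None, label: str = "main") -> EffectEstimate:
        horizon = self.horizon if horizon is None else horizon
        return contrast(self.predict_risk(1), self.predict_risk(0), horizon, label=label)


# ---------------------------------------------------------------------------
# propensity scores and stabilized weights


@dataclass
class PropensityModel:
    """Logistic model of treatment on baseline covariates."""

    coef: pd.Series
    design: _Design
    converged: bool
    marginal: float  # marginal Pr[A=1]

    def predict(self, cohort: pd.DataFrame) -> np.ndarray:
        X = self._matrix(cohort)
        lp = X @ self.coef.to_numpy()
        return 1.0 / (1.0 + np.exp(-lp))

    def _matrix(self, cohort: pd.DataFrame) -> np.ndarray:
        blocks = [np.ones((len(cohort), 1))]
        for cov in self.design.adjustment:
            x, _ = self.design._encode_one(cohort[cov], cov)
            blocks.append(x)
        return np.column_stack(blocks)


def fit_propensity(
    cohort: pd.DataFrame, adjustment: Sequence[str], tol: float = 1e-10, maxiter: int = 100
) -> tuple[PropensityModel, np.ndarray]:
    """Fit Pr[A=1 | L] by logistic regression; returns (model, probabilities)."""
    a = cohort["treatment"].to_numpy(dtype=float)
    if len(np.unique(a)) < 2:
        raise SingleClassError("both treatment arms must be non-empty")
    design = _Design(
        K=1, time_form="poly", degree=0, knots=None,
        adjustment=list(adjustment), products=False, include_treatment=False,
    )
    design.fit_covariates(cohort)
    blocks = [np.ones((len(cohort), 1))]
    names = ["intercept"]
    for cov in design.adjustment:
        x, xn = design._encode_one(cohort[cov], cov)
        blocks.append(x)
        names.extend(xn)
    X = np.column_stack(blocks)
    beta, _, converged, message = newton_logistic(X, a, tol=tol, maxiter=maxiter)
    if not converged:
        raise ModelConvergenceError(f"propensity model did not converge: {message}")
    model = PropensityModel(
        coef=pd.Series(beta, index=names),
        design=design,
        converged=converged,
        marginal=float(a.mean()),
    )
    return model, model.predict(cohort)


@dataclass
class WeightSet:
    """Stabilized inverse-probability-of-treatment weights.

    sw_i = Pr[A = a_i] / Pr[A = a_i | L_i]; the mean of stabilized weights is
    close to 1 in large samples, which :meth:`check_mean` asserts.
    """

    weights: np.ndarray
    marginal: float
    truncation: tuple[float, float] | None = None
    description: str = "stabilized IPW"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w <= 0) or not np.all(np.isfinite(w)):
            raise ValueError("weights must be positive and finite")
        self.weights = w

    def mean(self) -> float:
        return float(self.weights.mean())

    def check_mean(self, tolerance: float = 0.05) -> bool:
        return abs(self.mean() - 1.0) <= tolerance


def stabilized_weights(
    propensities: np.ndarray,
    cohort: pd.DataFrame,
    truncation: tuple[float, float] | None = None,
) -> WeightSet:
    """sw_i = marginal Pr[A=a_i] / Pr[A=a_i | L_i].

    ``truncation`` optionally gives symmetric percentile bounds, e.g.
    (1, 99); off by default.  Propensities of exactly 0 or 1 violate
    positivity and raise, listing the offending subjects.
    """
    ps = np.asarray(propensities, dtype=float)
    a = cohort["treatment"].to_numpy(dtype=float)
    bad = (ps <= 0.0) | (ps >= 1.0)
    if bad.any():
        ids = cohort.loc[bad, "id"].tolist() if "id" in cohort else list(np.flatnonzero(bad))
        raise PositivityError(
            f"propensity of 0 or 1 for subjects {ids[:20]}{'...' if len(ids) > 20 else ''}"
        )
    p1 = float(a.mean())
    sw = np.where(a == 1, p1 / ps, (1.0 - p1) / (1.0 - ps))
    if truncation is not None:
        lo, hi = np.percentile(sw, truncation)
        sw = np.clip(sw, lo, hi)
    return WeightSet(weights=sw, marginal=p1, truncation=truncation)


def ipw_risk_curves(
    cohort: pd.DataFrame,
    weights: WeightSet,
    outcome: str,
    K: int,
    coding: str | None = None,
    time_form: str = "indicator",
    products: bool = True,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> dict[int, RiskCurve]:
    """Weighted pooled logistic (treatment + time only) plug-in risk curves.

    Each subject's weight is carried to all of their person-period rows; the
    weighted fit uses no baseline covariates, so the per-arm plug-in curve is
    already marginal.
    """
    if len(weights.weights) != len(cohort):
        raise ValueError("weights must align row-wise with the cohort")
    tagged = cohort.reset_index(drop=True).copy()
    tagged["__weight__"] = weights.weights
    pp = expand_person_periods(tagged, outcome, K, coding)
    w_rows = pp.data.pop("__weight__").to_numpy(dtype=float)

    design = _Design(
        K=K, time_form=time_form, degree=3, knots=None,
        adjustment=[], products=products, include_treatment=True,
    )
    design.fit_covariates(pp.data)
    y = pp.data["event"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise SingleClassError("weighted person-period table has a single outcome class")
    X, names = design.build(pp.data, pp.data["interval"].to_numpy(), pp.data["treatment"].to_numpy(dtype=float))
    beta, _, converged, message = newton_logistic(X, y, sample_weight=w_rows, tol=tol, maxiter=maxiter)
    if not converged:
        raise ModelConvergenceError(f"weighted pooled logistic did not converge: {message}")

    k = np.arange(1, K + 1)
    tb, _ = design.time_basis(k)
    n_time = tb.shape[1]
    curves: dict[int, RiskCurve] = {}
    for arm in (0, 1):
        lp = tb @ beta[:n_time] + arm * beta[n_time]
        if products:
            lp = lp + arm * (tb[:, 1:] @ beta[n_time + 1 : n_time + n_time])
        h = 1.0 / (1.0 + np.exp(-lp))
        risks = 1.0 - np.cumprod(1.0 - h)
        curves[arm] = RiskCurve(strategy=arm, risks=risks, estimator="ipw", outcome=outcome)
    return curves


class IPWRiskEstimator(BaseEstimator):
    """Stabilized-IPW risk-curve estimator for a point treatment.

    Fits a logistic propensity model on the adjustment set, forms stabilized
    weights (untruncated by default), and estimates per-arm risk curves from
    a weighted pooled logistic model with treatment and time terms only.

    Attributes
    ----------
    propensity_model_ : PropensityModel
    propensities_ : ndarray
    weights_ : WeightSet
    risk_curves_ : dict[int, RiskCurve]
    """

    def __init__(
        self,
        outcome: str = "death",
        horizon: int = 12,
        coding: str | None = None,
        adjustment: Sequence[str] = (),
        time_form: str = "indicator",
        products: bool = True,
        truncation: tuple[float, float] | None = None,
        tol: float = 1e-8,
        maxiter: int = 100,
    ) -> None:
        self.outcome = outcome
        self.horizon = horizon
        self.coding = coding
        self.adjustment = adjustment
        self.time_form = time_form
        self.products = products
        self.truncation = truncation
        self.tol = tol
        self.maxiter = maxiter

    def fit(self, cohort: pd.DataFrame) -> "IPWRiskEstimator":
        data = cohort.reset_index(drop=True)
        self.propensity_model_, self.propensities_ = fit_propensity(
            data, list(self.adjustment), maxiter=self.maxiter
        )
        self.weights_ = stabilized_weights(self.propensities_, data, self.truncation)
        self.risk_curves_ = ipw_risk_curves(
            data, self.weights_, self.outcome, self.horizon, self.coding,
            time_form=self.time_form, products=self.products,
            tol=self.tol, maxiter=self.maxiter,
        )
        self.cohort_ = data
        return self

    def predict_risk(self, strategy: int) -> RiskCurve:
        if not hasattr(self, "risk_curves_"):
            raise RuntimeError("estimator is not fitted")
        return self.risk_curves_[int(strategy)]

    def effect(self, horizon: int | None = None, label: str = "main") -> EffectEstimate:
        horizon = self.horizon if horizon is None else horizon
        return contrast(self.predict_risk(1), self.predict_risk(0), horizon, label=label)

    def balance(self, covariates: Sequence[str] | None = None) -> pd.Series:
        """Weighted SMD per (numeric-encodable) covariate after IPW."""
        if not hasattr(self, "weights_"):
            raise RuntimeError("estimator is not fitted")
        covs = list(covariates) if covariates is not None else list(self.adjustment)
        out = {}
        for cov in covs:
            col = self.cohort_[cov]
            if pd.api.types.is_numeric_dtype(col):
                if col.isna().any():
                    tmp = self.cohort_[["treatment"]].copy()
                    tmp["__v__"] = col
                    tmp = tmp.dropna(subset=["__v__"])
                    # pairwise-complete weighted SMD
                    w = self.weights_.weights[~col.isna().to_numpy()]
                    out[cov] = standardized_mean_difference(tmp, "__v__", w)
                else:
                    out[cov] = standardized_mean_difference(
                        self.cohort_, cov, self.weights_.weights
                    )
            else:
                for level in col.dropna().unique():
                    tmp = self.cohort_[["treatment"]].copy()
                    tmp["__ind__"] = (col == level).astype(float)
                    out[f"{cov}[{level}]"] = standardized_mean_difference(
                        tmp, "__ind__", self.weights_.weights
                    )
        return pd.Series(out, name="weighted_smd")
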