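"""Person-period expansion and the pooled logistic discrete-time hazard model.

The cohort (one row per patient) is expanded into person-period rows, one
per at-risk interval, so that a logistic regression of the per-interval
event indicator approximates the discrete-time hazard h_k(a, L).  Three
outcome codings are supported:

``terminal``
    rows stop at the event (death analysis) or at the horizon;
``total-effect``
    for a nonfatal outcome with death competing: a patient who dies
    outcome-free keeps contributing event-free rows through the horizon, so
    the cumulative quantity is the total-effect risk with death treated as a
    non-event rather than a censoring event;
``censor-at-death``
    rows stop at the death interval (sensitivity analysis).

Model surface: treatment indicator, a flexible time-varying intercept
(per-interval indicators by default, polynomial or truncated-power spline
alternatives), treatment-by-time product terms on the same basis, and
baseline covariates.  Fitting uses an in-package deterministic Newton/IRLS
maximum-likelihood solver (the model is re-fit on every bootstrap resample,
so per-fit overhead matters); convergence and separation are surfaced
explicitly because the standardization step refuses non-converged fits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import ModelConvergenceError, SchemaError, SingleClassError, UnseenLevelError

__all__ = [
    "PersonPeriodTable",
    "expand_person_periods",
    "PooledLogisticHazard",
    "newton_logistic",
]


def newton_logistic(
    X: np.ndarray,
    y: np.ndarray,
    sample_weight: np.ndarray | None = None,
    tol: float = 1e-10,
    maxiter: int = 100,
    beta0: np.ndarray | None = None,
) -> tuple[np.ndarray, float, bool, str | None]:
    """Deterministic Newton/IRLS maximum likelihood for logistic regression.

    Full Newton steps with log-likelihood step-halving; convergence when the
    largest absolute step falls below ``tol`` (quadratic convergence then
    puts the coefficients at essentially machine precision).  Returns
    ``(beta, loglik, converged, message)``; separation or a singular Hessian
    is reported through ``converged=False`` rather than an exception so
    callers can decide (the bootstrap skips such resamples).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones(len(y)) if sample_weight is None else np.asarray(sample_weight, dtype=float)
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))

    def loglik(eta: np.ndarray) -> float:
        # numerically safe sum of w*(y*eta - log(1+exp(eta)))
        return float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))

    ll = loglik(eta)
    message = None
    for _ in range(maxiter):
        wt = w * mu * (1.0 - mu)
        grad = X.T @ (w * (y - mu))
        hess = (X * wt[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return beta, ll, False, "singular Hessian (separation or collinear design)"
        # step-halving keeps the likelihood monotone
        scale = 1.0
        for _half in range(40):
            cand = beta + scale * step
            eta_c = X @ cand
            ll_c = loglik(eta_c)
            if ll_c >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            return beta, ll, False, "step-halving failed to improve the likelihood"
        beta, eta, ll = cand, eta_c, ll_c
        mu = 1.0 / (1.0 + np.exp(-eta))
        if np.max(np.abs(scale * step)) < tol:
            return beta, ll, True, None
    return beta, ll, False, f"no convergence within {maxiter} iterations"

CODINGS = ("terminal", "total-effect", "censor-at-death")


@dataclass
class PersonPeriodTable:
    """Discrete-time expansion of a cohort for one outcome."""

    data: pd.DataFrame  # id, interval, treatment, covariates..., event
    outcome: str
    horizon: int
    coding: str

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def _interval_array(col: pd.Series) -> np.ndarray:
    return col.astype("Float64").to_numpy(dtype=float, na_value=np.inf)


def expand_person_periods(
    cohort: pd.DataFrame, outcome: str, horizon: int, coding: str | None = None
) -> PersonPeriodTable:
    """Expand one row per patient into one row per at-risk interval.

    Intervals are 1-based; an event in interval k means the patient was at
    risk at the start of k.  Events beyond the horizon count as event-free
    follow-up through the horizon.  Default coding: ``terminal`` for death,
    ``total-effect`` for MI.
    """
    if outcome not in {"death", "mi"}:
        raise ValueError(f"unknown outcome {outcome!r}")
    if coding is None:
        coding = "terminal" if outcome == "death" else "total-effect"
    if coding not in CODINGS:
        raise ValueError(f"unknown coding {coding!r}; expected one of {CODINGS}")
    for col in ("death_interval",) + (("mi_interval",) if outcome == "mi" else ()):
        if col not in cohort.columns:
            raise SchemaError(f"missing column {col!r}")

    death = _interval_array(cohort["death_interval"])
    if outcome == "death":
        event_time = death
    else:
        event_time = _interval_array(cohort["mi_interval"])

    K = int(horizon)
    has_event = event_time <= K
    if coding == "censor-at-death":
        if outcome != "mi":
            raise ValueError("censor-at-death coding applies to the MI outcome")
        # MI is evaluated before death within an interval, so an MI in the
        # death interval still counts; otherwise rows stop at death.
        stop = np.minimum(np.where(has_event, event_time, np.inf), np.minimum(death, K))
        n_rows = np.clip(stop, 0, K).astype(int)
        event_at_end = has_event & (event_time <= stop)
    elif coding == "total-effect":
        n_rows = np.where(has_event, event_time, K).astype(int)
        event_at_end = has_event
    else:  # terminal
        n_rows = np.where(has_event, event_time, K).astype(int)
        event_at_end = has_event

    idx = np.repeat(np.arange(len(cohort)), n_rows)
    interval = np.concatenate([np.arange(1, m + 1) for m in n_rows]) if len(cohort) else np.array([], int)
    data = cohort.iloc[idx].reset_index(drop=True)
    data = data.drop(columns=[c for c in ("death_interval", "mi_interval") if c in data.columns])
    data["interval"] = interval
    last_row = np.cumsum(n_rows) - 1
    event = np.zeros(int(n_rows.sum()), dtype=np.int64)
    ev_rows = last_row[(n_rows > 0) & event_at_end]
    event[ev_rows] = 1
    data["event"] = event
    return PersonPeriodTable(data=data, outcome=outcome, horizon=K, coding=coding)


# ---------------------------------------------------------------------------
# design-matrix construction


@dataclass
class _CovariateEncoding:
    kind: str  # "linear" | "categorical" | "binned"
    levels: list[str] | None = None
    bin_edges: np.ndarray | None = None


class _Design:
    """Fit-time design information: time basis + covariate encodings.

    Continuous adjustment covariates with any missing values at fit time are
    quartile-binned with an explicit "Missing" level (missing-indicator
    analysis); fully observed continuous covariates enter linearly.
    Categorical covariates are dummy-coded against their first observed
    level, with "Missing" as its own level when present.  Unseen levels at
    prediction time raise rather than being silently remapped.
    """

    def __init__(
        self,
        K: int,
        time_form: str,
        degree: int,
        knots: Sequence[float] | None,
        adjustment: Sequence[str],
        products: bool,
        include_treatment: bool,
    ) -> None:
        if time_form not in {"indicator", "poly", "spline"}:
            raise ValueError(f"unknown time form {time_form!r}")
        self.K = K
        self.time_form = time_form
        self.degree = degree
        self.knots = list(knots) if knots is not None else None
        self.adjustment = list(adjustment)
        self.products = products
        self.include_treatment = include_treatment
        self.encodings: dict[str, _CovariateEncoding] = {}
        self.columns: list[str] = []

    # -- time basis -------------------------------------------------------
    def time_basis(self, k: np.ndarray) -> tuple[np.ndarray, list[str]]:
        """Basis columns for the time-varying intercept at intervals ``k``."""
        k = np.asarray(k, dtype=float)
        if self.time_form == "indicator":
            cols = np.equal.outer(k, np.arange(1, self.K + 1)).astype(float)
            names = [f"t[{j}]" for j in range(1, self.K + 1)]
            return cols, names
        s = k / self.K
        if self.time_form == "poly":
            cols = [np.ones_like(s)] + [s**j for j in range(1, self.degree + 1)]
            names = ["intercept"] + [f"time^{j}" for j in range(1, self.degree + 1)]
            return np.column_stack(cols), names
        knots = self.knots or [0.25, 0.5, 0.75]
        cols = [np.ones_like(s), s, s**2, s**3]
        names = ["intercept", "time", "time^2", "time^3"]
        for q in knots:
            cols.append(np.clip(s - q, 0.0, None) ** 3)
            names.append(f"time_spline[{q:g}]")
        return np.column_stack(cols), names

    # -- covariates -------------------------------------------------------
    def fit_covariates(self, df: pd.DataFrame) -> None:
        for cov in self.adjustment:
            if cov not in df.columns:
                raise SchemaError(f"adjustment covariate {cov!r} not in table")
            col = df[cov]
            if pd.api.types.is_numeric_dtype(col) and col.dropna().nunique() > 10:
                if col.isna().any():
                    edges = np.unique(col.dropna().quantile([0.25, 0.5, 0.75]).to_numpy())
                    self.encodings[cov] = _CovariateEncoding("binned", bin_edges=edges)
                    levels = self._bin_labels(edges) + ["Missing"]
                    self.encodings[cov].levels = levels
                else:
                    self.encodings[cov] = _CovariateEncoding("linear")
            elif pd.api.types.is_numeric_dtype(col) and set(col.dropna().unique()) <= {0, 1} and not col.isna().any():
                self.encodings[cov] = _CovariateEncoding("linear")
            else:
                vals = col.astype(object)
                levels = sorted({str(v) for v in vals.dropna().unique()})
                if vals.isna().any():
                    levels.append("Missing")
                self.encodings[cov] = _CovariateEncoding("categorical", levels=levels)

    @staticmethod
    def _bin_labels(edges: np.ndarray) -> list[str]:
        return [f"bin{j}" for j in range(len(edges) + 1)]

    def _encode_one(self, col: pd.Series, cov: str) -> tuple[np.ndarray, list[str]]:
        enc = self.encodings[cov]
        if enc.kind == "linear":
            x = pd.to_numeric(col, errors="raise").to_numpy(dtype=float)
            if np.isnan(x).any():
                raise ValueError(
                    f"covariate {cov!r} was fully observed at fit time but has "
                    "missing values at prediction time"
                )
            return x[:, None], [cov]
        if enc.kind == "binned":
            x = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
            codes = np.searchsorted(enc.bin_edges, x, side="right")
            labels = np.array(self._bin_labels(enc.bin_edges) + ["Missing"], dtype=object)
            codes = np.where(np.isnan(x), len(labels) - 1, codes)
            observed = labels[codes.astype(int)]
            levels = enc.levels
        else:
            observed = np.where(col.isna(), "Missing", col.astype(object).astype(str))
            levels = enc.levels
            unseen = set(np.unique(observed)) - set(levels)
            if unseen:
                raise UnseenLevelError(
                    f"covariate {cov!r} has level(s) {sorted(unseen)} unseen at fit time"
                )
        # drop-first dummy coding
        out = np.column_stack([(observed == lv).astype(float) for lv in levels[1:]]) if len(levels) > 1 else np.empty((len(col), 0))
        names = [f"{cov}[{lv}]" for lv in levels[1:]]
        return out, names

    # -- full matrix ------------------------------------------------------
    def build(
        self, df: pd.DataFrame, interval: np.ndarray, treatment: np.ndarray
    ) -> tuple[np.ndarray, list[str]]:
        tb, tnames = self.time_basis(interval)
        blocks, names = [tb], list(tnames)
        if self.include_treatment:
            blocks.append(treatment[:, None].astype(float))
            names.append("treatment")
            if self.products:
                # product terms on the same basis, first column dropped to
                # avoid collinearity with the treatment main effect
                blocks.append(tb[:, 1:] * treatment[:, None])
                names.extend(f"treatment:{nm}" for nm in tnames[1:])
        for cov in self.adjustment:
            x, xn = self._encode_one(df[cov], cov)
            blocks.append(x)
            names.extend(xn)
        return np.column_stack(blocks) if blocks else np.empty((len(df), 0)), names


class PooledLogisticHazard(BaseEstimator):
    """Pooled logistic regression for discrete-time hazards.

    Parameters
    ----------
    time_form : {"indicator", "poly", "spline"}
        Shape of the time-varying intercept.  "indicator" (default) is
        saturated in time — one term per interval — which nests any smooth
        alternative and makes the no-covariate fit agree exactly with the
        Kaplan–Meier complement on uncensored data.
    degree : int
        Polynomial degree when ``time_form="poly"``.
    knots : sequence of float, optional
        Interior knots on the scaled time axis (k/K) for the spline basis.
    adjustment : sequence of str
        Baseline covariates entering the linear predictor.
    products : bool
        Include treatment-by-time product terms (same basis as the
        intercept, first column dropped).
    include_treatment : bool
        Set False for arm-specific fits.
    tol, maxiter : float, int
        Newton gradient tolerance and iteration cap; the fit is
        deterministic given the data and spec.

    Attributes
    ----------
    coef_ : pandas.Series
        Named coefficient vector.
    converged_ : bool
    loglik_ : float
    K_ : int
        Follow-up horizon the model was fitted on.
    """

    def __init__(
        self,
        time_form: str = "indicator",
        degree: int = 3,
        knots: Sequence[float] | None = None,
        adjustment: Sequence[str] = (),
        products: bool = True,
        include_treatment: bool = True,
        tol: float = 1e-10,
        maxiter: int = 100,
        warm_start: np.ndarray | None = None,
    ) -> None:
        self.time_form = time_form
        self.degree = degree
        self.knots = knots
        self.adjustment = adjustment
        self.products = products
        self.include_treatment = include_treatment
        self.tol = tol
        self.maxiter = maxiter
        self.warm_start = warm_start

    # ------------------------------------------------------------------
    def fit(
        self, pp: PersonPeriodTable, sample_weight: np.ndarray | None = None
    ) -> "PooledLogisticHazard":
        df = pp.data
        y = df["event"].to_numpy(dtype=float)
        if len(np.unique(y)) < 2:
            raise SingleClassError(
                f"person-period table for {pp.outcome!r} has a single outcome class"
            )
        design = _Design(
            K=pp.horizon,
            time_form=self.time_form,
            degree=self.degree,
            knots=self.knots,
            adjustment=self.adjustment,
            products=self.products,
            include_treatment=self.include_treatment,
        )
        design.fit_covariates(df)
        treatment = df["treatment"].to_numpy(dtype=float) if self.include_treatment else np.zeros(len(df))
        X, names = design.build(df, df["interval"].to_numpy(), treatment)
        self.design_ = design
        self.feature_names_ = names
        self.K_ = pp.horizon
        self.outcome_ = pp.outcome
        self.coding_ = pp.coding
        beta0 = None
        if self.warm_start is not None and len(np.asarray(self.warm_start)) == len(names):
            beta0 = np.asarray(self.warm_start, dtype=float)
        beta, ll, converged, message = newton_logistic(
            X, y, sample_weight=sample_weight, tol=self.tol, maxiter=self.maxiter,
            beta0=beta0,
        )
        self.coef_ = pd.Series(beta, index=names)
        self.loglik_ = ll
        self.converged_ = converged
        self.separation_message_ = None
        if not converged:
            worst = self.coef_.abs().idxmax()
            self.separation_message_ = (
                f"{message}; largest-magnitude term: {worst} = {self.coef_[worst]:.3g}"
            )
        return self

    def coefficients_json(self) -> str:
        """Serialize names, estimates and convergence metadata to JSON."""
        if not hasattr(self, "coef_"):
            raise RuntimeError("model is not fitted")
        payload = {
            "outcome": self.outcome_,
            "coding": self.coding_,
            "horizon": self.K_,
            "time_form": self.time_form,
            "converged": bool(self.converged_),
            "log_likelihood": None if np.isnan(self.loglik_) else self.loglik_,
            "coefficients": {k: float(v) for k, v in self.coef_.items()},
        }
        if self.separation_message_:
            payload["message"] = self.separation_message_
        return json.dumps(payload, indent=2)

    def _check_fitted(self) -> None:
        if not hasattr(self, "coef_"):
            raise RuntimeError("model is not fitted")
        if not self.converged_:
            raise ModelConvergenceError(self.separation_message_ or "fit did not converge")

    # ------------------------------------------------------------------
    def predict_hazard(self, rows: pd.DataFrame) -> np.ndarray:
        """Per-row hazard for a table with interval, treatment and covariates."""
        self._check_fitted()
        treatment = rows["treatment"].to_numpy(dtype=float) if self.include_treatment else np.zeros(len(rows))
        X, _ = self.design_.build(rows, rows["interval"].to_numpy(), treatment)
        lp = X @ self.coef_.to_numpy()
        return 1.0 / (1.0 + np.exp(-lp))

    def predict_hazard_matrix(self, cohort: pd.DataFrame, strategy: int, K: int | None = None) -> np.ndarray:
        """H[i, k] = h_k(strategy, L_i) for every cohort subject.

        Exploits additivity: the linear predictor decomposes into a
        per-interval part (time basis, treatment, products) and a per-subject
        covariate part, so no n*K expansion is materialized.
        """
        self._check_fitted()
        K = self.K_ if K is None else int(K)
        if K > self.K_ and self.time_form == "indicator":
            raise ValueError(f"horizon {K} beyond fitted indicator basis {self.K_}")
        k = np.arange(1, K + 1)
        tb, _ = self.design_.time_basis(k)
        beta = self.coef_.to_numpy()
        n_time = tb.shape[1]
        pos = n_time
        time_lp = tb @ beta[:n_time]
        a_lp = np.zeros(K)
        if self.include_treatment:
            a_coef = beta[pos]
            pos += 1
            a_lp += float(strategy) * a_coef
            if self.products:
                n_prod = n_time - 1
                a_lp += float(strategy) * (tb[:, 1:] @ beta[pos : pos + n_prod])
                pos += n_prod
        cov_lp = np.zeros(len(cohort))
        for cov in self.design_.adjustment:
            x, _ = self.design_._encode_one(cohort[cov], cov)
            n_cols = x.shape[1]
            cov_lp += x @ beta[pos : pos + n_cols]
            pos += n_cols
        lp = cov_lp[:, None] + (time_lp + a_lp)[None, :]
        return 1.0 / (1.0 + np.exp(-lp))


def fit_pooled_logistic(
    pp: PersonPeriodTable,
    adjustment: Sequence[str] = (),
    time_form: str = "indicator",
    products: bool = True,
    include_treatment: bool = True,
    **kwargs,
) -> PooledLogisticHazard:
    """Functional wrapper over :class:`PooledLogisticHazard`."""
    return PooledLogisticHazard(
        time_form=time_form,
        adjustment=adjustment,
        products=products,
        include_treatment=include_treatment,
        **kwargs,
    ).fit(pp)
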