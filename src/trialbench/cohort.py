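"""Cohort construction: eligibility, strategy assignment, balance, KM curves.

The analysis population of a point-treatment emulation is built by applying
ordered eligibility predicates (each reporting its own exclusion count, so
the result doubles as a selection flowchart), then assigning every patient
to the strategy their data were compatible with at baseline — the
observational analogue of a per-protocol population.  Baseline summaries and
standardized mean differences document confounding before and after
weighting; Kaplan–Meier curves provide the covariate-free nonparametric
comparator used throughout the test oracles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .errors import SchemaError, SingleClassError
from .results import RiskCurve

__all__ = [
    "EligibilityCriterion",
    "BalanceTable",
    "apply_eligibility",
    "assign_strategy",
    "baseline_table",
    "standardized_mean_difference",
    "kaplan_meier",
    "standard_criteria",
    "STRATEGY_LABELS",
]

STRATEGY_LABELS = {1: "thrombus aspiration", 0: "no thrombus aspiration"}


@dataclass
class EligibilityCriterion:
    """A named, pure keep-predicate over the registry table."""

    name: str
    predicate: Callable[[pd.DataFrame], pd.Series]

    def keep_mask(self, registry: pd.DataFrame) -> pd.Series:
        try:
            mask = self.predicate(registry)
        except KeyError as exc:  # pragma: no cover - message path
            raise SchemaError(
                f"criterion {self.name!r} references missing column {exc.args[0]!r}"
            ) from exc
        mask = pd.Series(np.asarray(mask, dtype=bool), index=registry.index)
        return mask


def apply_eligibility(
    registry: pd.DataFrame, criteria: Sequence[EligibilityCriterion]
) -> tuple[pd.DataFrame, list[dict[str, object]]]:
    """Apply criteria in declaration order; return (cohort, flowchart).

    The flowchart lists, per criterion, how many records the criterion
    excluded from what remained at that point — exclusion counts plus the
    final cohort size always sum back to the input size.
    """
    current = registry
    flowchart: list[dict[str, object]] = [{"stage": "input", "excluded": 0, "remaining": len(registry)}]
    for crit in criteria:
        keep = crit.keep_mask(current)
        excluded = int((~keep).sum())
        current = current.loc[keep]
        flowchart.append({"stage": crit.name, "excluded": excluded, "remaining": len(current)})
    return current.copy(), flowchart


def standard_criteria(
    min_age: float | None = 18.0,
    exclude_same_day_death: bool = True,
    min_stenosis: float | None = None,
    stenosis_col: str = "proportion_stenosis",
) -> list[EligibilityCriterion]:
    """Default criteria set: adult age, no death on the day of PCI, and an
    optional minimum culprit-artery stenosis (skippable as a sensitivity
    because of historical missingness in that variable)."""
    crits: list[EligibilityCriterion] = []
    if min_age is not None:
        crits.append(
            EligibilityCriterion(f"age >= {min_age:g}", lambda df, a=min_age: df["age"] >= a)
        )
    if exclude_same_day_death:
        crits.append(
            EligibilityCriterion(
                "no death on PCI day",
                lambda df: ~(df["death_interval"].fillna(-1).astype("int64") == 0),
            )
        )
    if min_stenosis is not None:
        crits.append(
            EligibilityCriterion(
                f"stenosis >= {min_stenosis:g}%",
                lambda df, s=min_stenosis, c=stenosis_col: df[c] >= s,
            )
        )
    return crits


def assign_strategy(cohort: pd.DataFrame, treatment_col: str = "treatment") -> pd.DataFrame:
    """Set strategy := treatment received (per-protocol analogue).

    Every record must have an observed treatment; offenders are listed.
    Adds ``strategy`` (0/1) and ``strategy_label`` columns.
    """
    if treatment_col not in cohort.columns:
        raise SchemaError(f"missing treatment column {treatment_col!r}")
    a = cohort[treatment_col]
    if a.isna().any():
        bad = cohort.loc[a.isna(), "id"].tolist() if "id" in cohort else list(cohort.index[a.isna()])
        raise ValueError(f"treatment missing for records: {bad[:20]}{'...' if len(bad) > 20 else ''}")
    out = cohort.copy()
    out["strategy"] = a.astype(np.int64)
    out["strategy_label"] = out["strategy"].map(STRATEGY_LABELS)
    return out


# ---------------------------------------------------------------------------
# balance diagnostics


def standardized_mean_difference(
    cohort: pd.DataFrame,
    covariate: str,
    weights: np.ndarray | pd.Series | None = None,
    arm_col: str = "treatment",
) -> float:
    """SMD d = (mean1 - mean0) / pooled SD, optionally weighted.

    Binary columns use proportions with the pooled binomial SD; the pooled SD
    is sqrt((s1^2 + s0^2)/2).  Missing values are dropped pairwise.  A zero
    pooled SD with unequal means returns +/-inf with a warning.
    """
    if covariate not in cohort.columns:
        raise SchemaError(f"covariate {covariate!r} not in cohort")
    x = pd.to_numeric(cohort[covariate], errors="raise").astype(float)
    a = cohort[arm_col].astype(int).to_numpy()
    w = np.ones(len(cohort)) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0) or (weights is not None and np.any(w[~x.isna().to_numpy()] <= 0)):
        raise ValueError("weights must be positive")
    ok = ~x.isna().to_numpy()
    stats = {}
    for arm in (0, 1):
        sel = ok & (a == arm)
        if not sel.any():
            raise SingleClassError(f"arm {arm} has no non-missing values for {covariate!r}")
        wa, xa = w[sel], x.to_numpy()[sel]
        m = np.sum(wa * xa) / np.sum(wa)
        v = np.sum(wa * (xa - m) ** 2) / np.sum(wa)
        stats[arm] = (m, v)
    (m0, v0), (m1, v1) = stats[0], stats[1]
    # binary columns: pooled binomial variance (identical to v when x in {0,1})
    pooled = np.sqrt((v1 + v0) / 2.0)
    if pooled == 0.0:
        if m1 == m0:
            return 0.0
        warnings.warn(f"zero pooled SD with unequal means for {covariate!r}", stacklevel=2)
        return float(np.inf) if m1 > m0 else float(-np.inf)
    return float((m1 - m0) / pooled)


@dataclass
class BalanceTable:
    """Tidy per-covariate, per-level baseline summary with SMDs."""

    table: pd.DataFrame
    arm_sizes: dict[int, int] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_markdown(self) -> str:
        return self.table.to_markdown(index=False)


def _is_continuous(col: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(col) and col.dropna().nunique() > 10


def baseline_table(
    cohort: pd.DataFrame,
    covariates: Sequence[str] | None = None,
    arm_col: str = "treatment",
    weights: np.ndarray | None = None,
) -> BalanceTable:
    """Per-arm baseline characteristics in registry-table style.

    Categorical/binary covariates get one row per level with count and
    percent of the arm total (an explicit "Missing" level when present);
    continuous covariates get a median (IQR) row plus a Missing row, with the
    SMD computed from means and SDs on the non-missing values.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    arms = {arm: cohort[cohort[arm_col] == arm] for arm in (0, 1)}
    for arm, df in arms.items():
        if len(df) == 0:
            raise SingleClassError(f"arm {arm} is empty")
    if covariates is None:
        reserved = {
            arm_col, "id", "index_date", "period", "strategy", "strategy_label",
            "death_interval", "mi_interval",
        }
        covariates = [c for c in cohort.columns if c not in reserved]
    rows: list[dict[str, object]] = []
    for cov in covariates:
        if cov not in cohort.columns:
            raise SchemaError(f"covariate {cov!r} not in cohort")
        col = cohort[cov]
        if _is_continuous(col):
            summ = {}
            for arm, df in arms.items():
                vals = pd.to_numeric(df[cov], errors="coerce")
                q1, med, q3 = vals.quantile([0.25, 0.5, 0.75])
                summ[arm] = f"{med:.1f} ({q1:.1f}, {q3:.1f})"
            rows.append(
                {
                    "covariate": cov,
                    "level": "median (IQR)",
                    "summary_1": summ[1],
                    "summary_0": summ[0],
                    "smd": standardized_mean_difference(cohort, cov, weights, arm_col),
                }
            )
            n_miss = {arm: int(arms[arm][cov].isna().sum()) for arm in (0, 1)}
            if n_miss[0] or n_miss[1]:
                rows.append(
                    {
                        "covariate": cov,
                        "level": "Missing",
                        "n_1": n_miss[1],
                        "pct_1": round(100.0 * n_miss[1] / len(arms[1]), 1),
                        "n_0": n_miss[0],
                        "pct_0": round(100.0 * n_miss[0] / len(arms[0]), 1),
                    }
                )
        else:
            levels = col.dropna().unique().tolist()
            if set(levels) <= {0, 1}:
                levels = [1]  # binary: one row for the positive level
            else:
                levels = sorted(levels, key=str)
            has_missing = col.isna().any()
            for level in levels:
                entry: dict[str, object] = {"covariate": cov, "level": str(level)}
                for arm, df in arms.items():
                    n = int((df[cov] == level).sum())
                    entry[f"n_{arm}"] = n
                    entry[f"pct_{arm}"] = round(100.0 * n / len(df), 1)
                indicator = (cohort[cov] == level).astype(float)
                tmp = cohort[[arm_col]].copy()
                tmp["__ind__"] = indicator
                entry["smd"] = standardized_mean_difference(tmp, "__ind__", weights, arm_col)
                rows.append(entry)
            if has_missing:
                entry = {"covariate": cov, "level": "Missing"}
                for arm, df in arms.items():
                    n = int(df[cov].isna().sum())
                    entry[f"n_{arm}"] = n
                    entry[f"pct_{arm}"] = round(100.0 * n / len(df), 1)
                rows.append(entry)
    table = pd.DataFrame(rows)
    col_order = [c for c in ("covariate", "level", "n_1", "pct_1", "n_0", "pct_0",
                             "summary_1", "summary_0", "smd") if c in table.columns]
    return BalanceTable(table[col_order], {arm: len(df) for arm, df in arms.items()})


# ---------------------------------------------------------------------------
# Kaplan-Meier comparator


def _event_times(
    cohort: pd.DataFrame, outcome: str, horizon: int, censor_at_death: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    death = cohort["death_interval"].astype("Float64").to_numpy(dtype=float, na_value=np.inf)
    if outcome == "death":
        event_time = death
    elif outcome == "mi":
        event_time = cohort["mi_interval"].astype("Float64").to_numpy(dtype=float, na_value=np.inf)
    else:
        raise ValueError(f"unknown outcome {outcome!r}")
    if outcome == "mi" and censor_at_death:
        censor_time = np.minimum(death, horizon)
    else:
        censor_time = np.full(len(cohort), float(horizon))
    event = event_time <= censor_time
    duration = np.where(event, event_time, censor_time)
    return duration, event


def kaplan_meier(
    cohort: pd.DataFrame,
    arm: int,
    outcome: str,
    horizon: int,
    censor_at_death: bool = False,
    arm_col: str = "treatment",
    weights: np.ndarray | None = None,
) -> RiskCurve:
    """Product-limit cumulative risk on the discrete interval grid.

    For MI the default follows the total-effect convention (a death without
    prior MI contributes event-free follow-up through the horizon);
    ``censor_at_death=True`` switches to censoring at the death interval.
    With no censoring before the horizon the curve equals the empirical
    cumulative incidence.
    """
    sel = cohort[arm_col] == arm
    if not sel.any():
        raise SingleClassError(f"arm {arm} is empty")
    sub = cohort.loc[sel]
    duration, event = _event_times(sub, outcome, horizon, censor_at_death)
    kmf = KaplanMeierFitter()
    w = None if weights is None else np.asarray(weights, dtype=float)[sel.to_numpy()]
    kmf.fit(duration, event_observed=event, weights=w)
    surv = kmf.survival_function_at_times(np.arange(1, horizon + 1)).to_numpy(dtype=float)
    return RiskCurve(strategy=arm, risks=1.0 - surv, estimator="kaplan-meier", outcome=outcome)
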