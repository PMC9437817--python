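"""Bootstrap confidence intervals, trial benchmarking, subgroup analyses.

Confidence intervals are nonparametric percentile bootstrap: subjects (not
person-period rows) are resampled with replacement and the entire estimation
pipeline — model fit plus standardization — is re-run on each resample.
Benchmarking compares the emulation's effect estimates against an index
randomized trial's published results using an explicit decision-concordance
rule; subgroup analyses re-run the full pipeline within baseline strata.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ModelConvergenceError, PositivityError, SingleClassError
from .results import EffectEstimate

__all__ = [
    "BootstrapResult",
    "IndexTrialResult",
    "BenchmarkReport",
    "bootstrap_ci",
    "bootstrap_statistics",
    "percentile_interval",
    "benchmark",
    "stratified_estimates",
    "default_stratifiers",
]

logger = logging.getLogger(__name__)

# failures that invalidate a single resample rather than the whole analysis
_SKIPPABLE = (SingleClassError, ModelConvergenceError, PositivityError, np.linalg.LinAlgError)


@dataclass
class BootstrapResult:
    """Point estimate plus percentile bootstrap interval."""

    point: float
    samples: np.ndarray
    lower: float
    upper: float
    B: int
    seed: int
    n_skipped: int = 0

    @property
    def ci(self) -> tuple[float, float]:
        return (self.lower, self.upper)


def percentile_interval(samples: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """95% percentile interval as order statistics at ranks
    ceil(0.025 B) and ceil(0.975 B) (1-based)."""
    s = np.sort(np.asarray(samples, dtype=float))
    B = len(s)
    if B == 0:
        raise ValueError("no bootstrap samples")
    alpha = (1.0 - level) / 2.0
    # guard against ceil(25.000000000000004) -> 26 float artifacts
    lo = max(math.ceil(alpha * B - 1e-9), 1)
    hi = max(math.ceil((1.0 - alpha) * B - 1e-9), 1)
    return float(s[lo - 1]), float(s[hi - 1])


def bootstrap_statistics(
    analysis: Callable[[pd.DataFrame], Mapping[str, float]],
    cohort: pd.DataFrame,
    B: int = 200,
    seed: int = 0,
    max_skip_frac: float = 0.1,
    level: float = 0.95,
) -> dict[str, BootstrapResult]:
    """Subject-level percentile bootstrap of a dict-valued analysis.

    ``analysis`` maps a cohort table to named statistics; the whole pipeline
    is re-run on each of B with-replacement resamples of subjects.
    Resamples on which the analysis degenerates (single outcome class,
    non-convergence, positivity violation) are skipped and logged; more than
    ``max_skip_frac`` skipped resamples is a hard error.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    point = dict(analysis(cohort))
    rng = np.random.default_rng(seed)
    n = len(cohort)
    samples: dict[str, list[float]] = {k: [] for k in point}
    n_skipped = 0
    for b in range(B):
        idx = rng.integers(0, n, n)
        resample = cohort.iloc[idx].reset_index(drop=True)
        try:
            stat = analysis(resample)
        except _SKIPPABLE as exc:
            n_skipped += 1
            logger.info("bootstrap resample %d skipped: %s", b, exc)
            continue
        for k in samples:
            samples[k].append(float(stat[k]))
    if n_skipped > max_skip_frac * B:
        raise RuntimeError(
            f"{n_skipped}/{B} bootstrap resamples skipped (> {max_skip_frac:.0%})"
        )
    out: dict[str, BootstrapResult] = {}
    for k, vals in samples.items():
        arr = np.asarray(vals, dtype=float)
        lo, hi = percentile_interval(arr, level)
        out[k] = BootstrapResult(
            point=float(point[k]), samples=arr, lower=lo, upper=hi,
            B=B, seed=seed, n_skipped=n_skipped,
        )
    return out


def bootstrap_ci(
    analysis: Callable[[pd.DataFrame], float],
    cohort: pd.DataFrame,
    B: int = 200,
    seed: int = 0,
    max_skip_frac: float = 0.1,
    level: float = 0.95,
) -> BootstrapResult:
    """Scalar convenience wrapper over :func:`bootstrap_statistics`."""
    res = bootstrap_statistics(
        lambda df: {"stat": float(analysis(df))}, cohort, B, seed, max_skip_frac, level
    )
    return res["stat"]


# ---------------------------------------------------------------------------
# benchmarking against the index randomized trial


@dataclass
class IndexTrialResult:
    """One published index-trial result for a given outcome and horizon.

    ``effect`` is the trial's ratio (or difference) estimate with its 95%
    CI; ``effect_type`` records the published scale — a hazard ratio is
    accepted as the trial-side ratio but flagged as an estimand-scale
    caveat in the benchmark report.
    """

    outcome: str
    horizon: int
    effect: float
    ci: tuple[float, float]
    effect_type: str = "hazard_ratio"  # "hazard_ratio" | "risk_ratio" | "risk_difference"
    risk1: float | None = None
    risk0: float | None = None
    source: str = "index trial"

    def __post_init__(self) -> None:
        lo, hi = self.ci
        if not lo <= self.effect <= hi:
            raise ValueError(f"trial CI {self.ci} does not contain point {self.effect}")

    @property
    def null_value(self) -> float:
        return 0.0 if self.effect_type == "risk_difference" else 1.0

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "IndexTrialResult":
        return cls(
            outcome=str(d["outcome"]),
            horizon=int(d["horizon"]),
            effect=float(d["effect"]),
            ci=(float(d["ci"][0]), float(d["ci"][1])),
            effect_type=str(d.get("effect_type", "hazard_ratio")),
            risk1=None if d.get("risk1") is None else float(d["risk1"]),
            risk0=None if d.get("risk0") is None else float(d["risk0"]),
            source=str(d.get("source", "index trial")),
        )

    @classmethod
    def load_json(cls, path) -> list["IndexTrialResult"]:
        with open(path) as fh:
            entries = json.load(fh)
        return [cls.from_dict(e) for e in entries]


def _includes(ci: tuple[float, float], value: float) -> bool:
    return ci[0] <= value <= ci[1]


def _overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


@dataclass
class BenchmarkReport:
    """Per-outcome emulation-vs-trial agreement and an overall verdict."""

    rows: list[dict[str, object]]
    success: bool

    def to_dict(self) -> dict[str, object]:
        return {"success": self.success, "outcomes": self.rows}

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_markdown(self) -> str:
        lines = [
            "| outcome | horizon | trial | emulation | CI overlap | concordant |",
            "|---|---|---|---|---|---|",
        ]
        for r in self.rows:
            lines.append(
                f"| {r['outcome']} | {r['horizon']} | "
                f"{r['trial_effect']:.2f} ({r['trial_ci'][0]:.2f}, {r['trial_ci'][1]:.2f}) | "
                f"{r['emulation_effect']:.2f} ({r['emulation_ci'][0]:.2f}, {r['emulation_ci'][1]:.2f}) | "
                f"{r['ci_overlap']} | {r['concordant']} |"
            )
        lines.append(f"\nOverall benchmarking success: **{self.success}**")
        return "\n".join(lines)


def benchmark(
    emulation: Sequence[EffectEstimate],
    trial: Sequence[IndexTrialResult],
    scale: str = "ratio",
) -> BenchmarkReport:
    """Compare emulation estimates with index-trial results outcome by outcome.

    Decision-concordance rule: both studies' CIs include the null (no
    material benefit either way), or both exclude it on the same side.
    Benchmarking succeeds only if every matched outcome is concordant.
    Ratio-scale comparisons against a published hazard ratio are carried out
    directly but flagged (``scale_caveat``) as an estimand-scale caveat.
    """
    trial_by_key = {(t.outcome, t.horizon): t for t in trial}
    rows = []
    for est in sorted(emulation, key=lambda e: (e.outcome, e.horizon)):
        key = (est.outcome, est.horizon)
        if key not in trial_by_key:
            raise ValueError(f"no index-trial result for outcome/horizon {key}")
        t = trial_by_key.pop(key)
        if scale == "ratio":
            if est.rr_ci is None:
                raise ValueError(f"emulation estimate for {key} lacks a ratio CI")
            emu_effect, emu_ci, null = est.rr, est.rr_ci, 1.0
        else:
            if est.rd_ci is None:
                raise ValueError(f"emulation estimate for {key} lacks an RD CI")
            emu_effect, emu_ci, null = est.rd, est.rd_ci, 0.0
        trial_null = _includes(t.ci, t.null_value)
        emu_null = _includes(emu_ci, null)
        if trial_null and emu_null:
            concordant = True
        elif not trial_null and not emu_null:
            concordant = (t.effect > t.null_value) == (emu_effect > null)
        else:
            concordant = False
        rows.append(
            {
                "outcome": est.outcome,
                "horizon": est.horizon,
                "trial_effect": t.effect,
                "trial_ci": tuple(t.ci),
                "trial_effect_type": t.effect_type,
                "emulation_effect": emu_effect,
                "emulation_ci": tuple(emu_ci),
                "ci_overlap": _overlap(t.ci, emu_ci),
                "trial_null_compatible": trial_null,
                "emulation_null_compatible": emu_null,
                "concordant": concordant,
                "scale_caveat": t.effect_type == "hazard_ratio" and scale == "ratio",
            }
        )
    if trial_by_key:
        raise ValueError(f"unmatched index-trial outcomes: {sorted(trial_by_key)}")
    return BenchmarkReport(rows=rows, success=all(r["concordant"] for r in rows))


# ---------------------------------------------------------------------------
# subgroup / period-stratified analyses


def default_stratifiers(age_cut: float = 65.0) -> dict[str, Callable[[pd.DataFrame], pd.Series]]:
    """Stratifiers of the subgroup analysis: sex, age (<65/>=65), diabetes,
    previous PCI, previous MI, and calendar period."""
    return {
        "sex": lambda df: np.where(df["female"] == 1, "female", "male"),
        "age": lambda df: np.where(df["age"] < age_cut, f"<{age_cut:g}", f">={age_cut:g}"),
        "diabetes": lambda df: np.where(df["diabetes"] == 1, "yes", "no"),
        "previous_pci": lambda df: np.where(df["prev_pci"] == 1, "yes", "no"),
        "previous_mi": lambda df: np.where(df["prev_mi"] == 1, "yes", "no"),
        "period": lambda df: df["period"],
    }


def stratified_estimates(
    cohort: pd.DataFrame,
    stratifiers: Mapping[str, Callable[[pd.DataFrame], pd.Series] | str],
    estimator_factory: Callable[[], object],
    horizon: int | None = None,
    B: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the full pipeline (fit + standardize + bootstrap) within strata.

    ``stratifiers`` maps a name to a column name or a callable producing a
    label per row; the labels must partition the cohort.  ``estimator_factory``
    builds a fresh (unfitted) risk estimator per stratum.  Strata in which an
    arm has no events are flagged ``unstable`` rather than dropped.
    """
    rows = []
    for s_idx, (name, spec) in enumerate(stratifiers.items()):
        labels = pd.Series(
            cohort[spec] if isinstance(spec, str) else spec(cohort), index=cohort.index
        )
        if labels.isna().any():
            raise ValueError(f"stratifier {name!r} produced missing labels")
        for l_idx, level in enumerate(sorted(labels.unique(), key=str)):
            sub = cohort.loc[labels == level].reset_index(drop=True)
            est = estimator_factory()
            h = horizon if horizon is not None else est.horizon

            def run(df: pd.DataFrame, _est_factory=estimator_factory, _h=h) -> dict[str, float]:
                e = _est_factory().fit(df)
                eff = e.effect(_h)
                return {"rd": eff.rd, "rr": eff.rr}

            stratum_seed = (seed + 10_007 * s_idx + 101 * l_idx) % (2**31)
            outcome_col = "death_interval" if est.outcome == "death" else "mi_interval"
            events = (sub[outcome_col].astype("Float64") <= h).sum()
            unstable = False
            rd_ci = rr_ci = (float("nan"), float("nan"))
            try:
                est.fit(sub)
                eff = est.effect(h, label=f"{name}={level}")
            except _SKIPPABLE as exc:
                # e.g. no events in the stratum: flag, never drop silently
                logger.warning("stratum %s=%s unstable: %s", name, level, exc)
                eff = EffectEstimate(
                    outcome=est.outcome, horizon=h, risk1=float("nan"),
                    risk0=float("nan"), rd=float("nan"), rr=float("nan"),
                    estimator="gformula", label=f"{name}={level}",
                )
                unstable = True
            if not unstable:
                try:
                    boot = bootstrap_statistics(run, sub, B=B, seed=stratum_seed)
                    rd_ci, rr_ci = boot["rd"].ci, boot["rr"].ci
                except (RuntimeError, *_SKIPPABLE):
                    unstable = True
            arm_events = [
                int((sub.loc[sub["treatment"] == arm, outcome_col].astype("Float64") <= h).sum())
                for arm in (0, 1)
            ]
            unstable = unstable or min(arm_events) == 0
            rows.append(
                {
                    "stratifier": name,
                    "stratum": str(level),
                    "outcome": est.outcome,
                    "horizon": h,
                    "n": len(sub),
                    "n_events": int(events),
                    "risk1": eff.risk1,
                    "risk0": eff.risk0,
                    "rd": eff.rd,
                    "rd_lower": rd_ci[0],
                    "rd_upper": rd_ci[1],
                    "rr": eff.rr,
                    "rr_lower": rr_ci[0],
                    "rr_upper": rr_ci[1],
                    "unstable": unstable,
                }
            )
    return pd.DataFrame(rows)
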