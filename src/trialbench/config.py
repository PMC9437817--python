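"""Configuration parsing for generation and analysis runs (YAML or JSON)."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

from .simulate import (
    ConfigurationError,
    CovariateSpec,
    GenerationConfig,
    HazardModel,
    LogisticModel,
)

__all__ = [
    "AnalysisConfig",
    "load_mapping",
    "generation_config_from_dict",
    "analysis_config_from_file",
]


def load_mapping(path: str | Path) -> dict[str, Any]:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def _logistic_model(d: Mapping[str, Any] | None) -> LogisticModel | None:
    if d is None:
        return None
    return LogisticModel(intercept=float(d.get("intercept", 0.0)), coef=dict(d.get("coef", {})))


def _hazard_model(d: Mapping[str, Any], name: str) -> HazardModel:
    if d is None:
        raise ConfigurationError(f"missing hazard model {name!r}")
    return HazardModel(
        baseline=d.get("baseline", 0.0),
        coef=dict(d.get("coef", {})),
        treatment_log_odds=float(d.get("treatment_log_odds", 0.0)),
    )


def generation_config_from_dict(d: Mapping[str, Any]) -> GenerationConfig:
    covariates = [CovariateSpec(**c) for c in d["covariates"]]
    corr = d.get("correlation")
    return GenerationConfig(
        n_subjects=int(d["n_subjects"]),
        n_intervals=int(d["n_intervals"]),
        covariates=covariates,
        correlation=None if corr is None else np.asarray(corr, dtype=float),
        treatment_model=_logistic_model(d.get("treatment_model", {})),
        period_treatment_model=_logistic_model(d.get("period_treatment_model")),
        death_hazard=_hazard_model(d.get("death_hazard"), "death_hazard"),
        mi_hazard=_hazard_model(d.get("mi_hazard"), "mi_hazard"),
        period_prob=float(d.get("period_prob", 0.0)),
        seed=int(d.get("seed", 0)),
    )


@dataclass
class AnalysisConfig:
    """Single-file description of an emulation run.

    Every sensitivity toggle maps to exactly one pipeline variant:
    ``complete_case`` drops subjects with missing adjustment covariates,
    ``age_sex_only`` shrinks the adjustment set, ``censor_at_death`` switches
    the MI coding, ``arm_specific`` fits per-arm outcome models.
    """

    registry: str
    outcomes: Sequence[str] = ("death", "mi")
    horizons: Sequence[int] = (12, 36)
    interval_months: int = 1
    adjustment: Sequence[str] = ()
    estimators: Sequence[str] = ("gformula",)
    # smooth basis by default: a saturated per-interval basis with product
    # terms needs events in every arm-interval cell, which long horizons
    # rarely provide
    time_form: str = "poly"
    B: int = 200
    seed: int = 0
    eligibility: Mapping[str, Any] = field(default_factory=dict)
    stratifiers: Sequence[str] = ()
    complete_case: bool = False
    age_sex_only: bool = False
    censor_at_death: bool = False
    arm_specific: bool = False
    trial_results: str | None = None

    def __post_init__(self) -> None:
        bad = set(self.estimators) - {"gformula", "ipw"}
        if bad:
            raise ConfigurationError(f"unknown estimators: {sorted(bad)}")
        bad = set(self.outcomes) - {"death", "mi"}
        if bad:
            raise ConfigurationError(f"unknown outcomes: {sorted(bad)}")

    @property
    def effective_adjustment(self) -> list[str]:
        if self.age_sex_only:
            return [c for c in ("age", "female", "sex") if c in self.adjustment] or ["age", "female"]
        return list(self.adjustment)

    def mi_coding(self) -> str:
        return "censor-at-death" if self.censor_at_death else "total-effect"


def analysis_config_from_file(path: str | Path) -> AnalysisConfig:
    return AnalysisConfig(**load_mapping(path))
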