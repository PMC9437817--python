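"""Shared fixtures: small generating laws with exactly computable truths."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import trialbench as tb
from trialbench.simulate import CovariateSpec, GenerationConfig, HazardModel, LogisticModel


def two_binary_config(
    n: int = 2000,
    seed: int = 0,
    treatment_effect: float = 0.0,
    confounded: bool = True,
    K: int = 12,
    h_death: float = 0.02,
    h_mi: float = 0.012,
    period_prob: float = 0.0,
) -> GenerationConfig:
    """Two independent binary covariates: the oracle enumerates 4 strata
    exactly.  Confounding (when on) makes treated subjects sicker, so the
    unadjusted comparison is biased upward."""
    covs = [CovariateSpec("x1", "binary", p=0.4), CovariateSpec("x2", "binary", p=0.25)]
    tm = LogisticModel(intercept=-1.2, coef={"x1": 0.8, "x2": 0.6} if confounded else {})
    death = HazardModel(
        baseline=h_death, coef={"x1": 0.7, "x2": 0.5}, treatment_log_odds=treatment_effect
    )
    mi = HazardModel(baseline=h_mi, coef={"x1": 0.4}, treatment_log_odds=0.0)
    return GenerationConfig(
        n_subjects=n, n_intervals=K, covariates=covs, treatment_model=tm,
        death_hazard=death, mi_hazard=mi, period_prob=period_prob, seed=seed,
    )


def make_cohort(death, mi, treatment, **extra) -> pd.DataFrame:
    """Hand-built cohort from per-subject event intervals (None = no event)."""
    n = len(treatment)
    df = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "treatment": np.asarray(treatment, dtype=np.int64),
            "death_interval": pd.array([d if d is not None else pd.NA for d in death], dtype="Int64"),
            "mi_interval": pd.array([m if m is not None else pd.NA for m in mi], dtype="Int64"),
        }
    )
    for k, v in extra.items():
        df[k] = v
    return df


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    cfg = two_binary_config(n=3000, seed=5)
    return tb.assign_strategy(tb.generate_registry(cfg))


@pytest.fixture(scope="session")
def small_config() -> GenerationConfig:
    return two_binary_config(n=3000, seed=5)
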