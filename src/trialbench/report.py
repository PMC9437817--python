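"""End-to-end runs and report-bundle output.

``run_generate`` writes a synthetic registry with its ground-truth oracle;
``run_emulate`` executes eligibility -> strategy assignment -> model fit ->
standardization (and/or IPW) -> bootstrap for every configured outcome and
horizon and writes the full bundle (flowchart, balance table, risk curves,
effects, survival plot, run manifest).  Outputs are deterministic given the
registry, the config and the seed — the manifest records enough to reproduce
them bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import __version__
from .cohort import apply_eligibility, assign_strategy, baseline_table, standard_criteria
from .config import AnalysisConfig, generation_config_from_dict
from .estimators import GFormulaRiskEstimator, IPWRiskEstimator
from .inference import (
    IndexTrialResult,
    benchmark,
    bootstrap_statistics,
    default_stratifiers,
    stratified_estimates,
)
from .simulate import GenerationConfig, TrueEffectOracle, generate_registry

logger = logging.getLogger(__name__)

plt.rcParams["svg.hashsalt"] = "trialbench"  # deterministic SVG ids


def _sha256(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def _manifest(outdir: Path, config_obj, seed: int, extra: Mapping[str, object]) -> None:
    manifest = {
        "version": __version__,
        "seed": int(seed),
        "config_sha256": _sha256(json.dumps(config_obj, sort_keys=True, default=str).encode()),
        **extra,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run_generate(config: GenerationConfig | Mapping, outdir: str | Path) -> pd.DataFrame:
    """Write registry.csv plus an oracle.json of true risks/RD/RR."""
    if not isinstance(config, GenerationConfig):
        config = generation_config_from_dict(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    registry = generate_registry(config)
    registry.to_csv(outdir / "registry.csv", index=False)
    oracle = TrueEffectOracle(config)
    horizons = sorted({min(12, config.n_intervals), config.n_intervals})
    truth = {}
    for outcome in ("death", "mi"):
        for h in horizons:
            truth[f"{outcome}_risk1_{h}"] = oracle.true_risk(1, h, outcome)
            truth[f"{outcome}_risk0_{h}"] = oracle.true_risk(0, h, outcome)
            truth[f"{outcome}_rd_{h}"] = oracle.true_rd(h, outcome)
            truth[f"{outcome}_rr_{h}"] = oracle.true_rr(h, outcome)
    (outdir / "oracle.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    cfg_summary = {"n_subjects": config.n_subjects, "n_intervals": config.n_intervals,
                   "seed": config.seed, "covariates": config.names}
    _manifest(outdir, cfg_summary, config.seed, {"n_rows": len(registry), "stage": "generate"})
    logger.info("generate: wrote %d rows to %s", len(registry), outdir)
    return registry


def _load_registry(cfg: AnalysisConfig) -> pd.DataFrame:
    df = pd.read_csv(cfg.registry)
    for col in ("death_interval", "mi_interval"):
        if col in df.columns:
            df[col] = pd.array(df[col], dtype="Int64")
    return df


def build_cohort(cfg: AnalysisConfig, registry: pd.DataFrame | None = None):
    """Eligibility + strategy assignment; returns (cohort, flowchart)."""
    if registry is None:
        registry = _load_registry(cfg)
    criteria = standard_criteria(**cfg.eligibility) if cfg.eligibility else standard_criteria()
    cohort, flowchart = apply_eligibility(registry, criteria)
    cohort = assign_strategy(cohort)
    for stage in flowchart:
        logger.info("eligibility %-28s excluded=%-6s remaining=%s",
                    stage["stage"], stage["excluded"], stage["remaining"])
    return cohort, flowchart


def _make_estimator(cfg: AnalysisConfig, estimator: str, outcome: str, horizon: int):
    coding = cfg.mi_coding() if outcome == "mi" else "terminal"
    if estimator == "gformula":
        return GFormulaRiskEstimator(
            outcome=outcome, horizon=horizon, coding=coding,
            adjustment=cfg.effective_adjustment, time_form=cfg.time_form,
            arm_specific=cfg.arm_specific, complete_case=cfg.complete_case,
        )
    return IPWRiskEstimator(
        outcome=outcome, horizon=horizon, coding=coding,
        adjustment=cfg.effective_adjustment, time_form=cfg.time_form,
    )


def run_emulate(cfg: AnalysisConfig, outdir: str | Path, registry: pd.DataFrame | None = None) -> dict:
    """Full emulation run; writes the report bundle and returns it as a dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort, flowchart = build_cohort(cfg, registry)
    (outdir / "flowchart.json").write_text(json.dumps(flowchart, indent=2))
    balance = baseline_table(cohort, covariates=list(cfg.adjustment) or None)
    balance.to_csv(outdir / "balance.csv")
    (outdir / "balance.md").write_text(balance.to_markdown())

    max_h = max(cfg.horizons)
    curves_rows, effects = [], []
    fitted = {}
    for estimator in cfg.estimators:
        for outcome in cfg.outcomes:
            est = _make_estimator(cfg, estimator, outcome, max_h).fit(cohort)
            fitted[(estimator, outcome)] = est
            for arm in (0, 1):
                curve = est.predict_risk(arm)
                for k, r in enumerate(curve.risks, start=1):
                    curves_rows.append(
                        {"estimator": estimator, "outcome": outcome, "strategy": arm,
                         "interval": k, "risk": r}
                    )
            for h in cfg.horizons:
                effects.append(est.effect(h, label=f"{estimator}"))

    # one bootstrap loop re-running every configured analysis per resample
    def analysis(df: pd.DataFrame) -> dict[str, float]:
        out = {}
        for estimator in cfg.estimators:
            for outcome in cfg.outcomes:
                e = _make_estimator(cfg, estimator, outcome, max_h).fit(df)
                for h in cfg.horizons:
                    eff = e.effect(h)
                    key = f"{estimator}_{outcome}_{h}"
                    out[f"{key}_rd"] = eff.rd
                    out[f"{key}_rr"] = eff.rr
                    out[f"{key}_risk1"] = eff.risk1
                    out[f"{key}_risk0"] = eff.risk0
        return out

    boot = bootstrap_statistics(analysis, cohort, B=cfg.B, seed=cfg.seed)
    for eff in effects:
        key = f"{eff.label}_{eff.outcome}_{eff.horizon}"
        eff.rd_ci = boot[f"{key}_rd"].ci
        eff.rr_ci = boot[f"{key}_rr"].ci
        eff.risk1_ci = boot[f"{key}_risk1"].ci
        eff.risk0_ci = boot[f"{key}_risk0"].ci

    pd.DataFrame(curves_rows).to_csv(outdir / "risk_curves.csv", index=False)
    (outdir / "effects.json").write_text(
        json.dumps([e.to_dict() for e in effects], indent=2)
    )
    plot_risk_curves(fitted, outdir / "curves.svg")

    bundle = {
        "flowchart": flowchart,
        "effects": [e.to_dict() for e in effects],
        "n_cohort": len(cohort),
    }
    if cfg.trial_results:
        trial = IndexTrialResult.load_json(cfg.trial_results)
        matched_h = {(t.outcome, t.horizon) for t in trial}
        emu = [e for e in effects if (e.outcome, e.horizon) in matched_h
               and e.label == cfg.estimators[0]]
        report = benchmark(emu, trial)
        report.to_json(outdir / "benchmark.json")
        (outdir / "benchmark.md").write_text(report.to_markdown())
        bundle["benchmark"] = report.to_dict()
    _manifest(outdir, cfg.__dict__, cfg.seed, {"n_cohort": len(cohort), "stage": "emulate"})
    return bundle


def run_subgroups(cfg: AnalysisConfig, outdir: str | Path, registry: pd.DataFrame | None = None,
                  outcome: str = "death", horizon: int | None = None) -> pd.DataFrame:
    """Subgroup (and period-stratified) analyses at 1 year by default."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort, _ = build_cohort(cfg, registry)
    h = horizon if horizon is not None else min(cfg.horizons)
    all_strat = default_stratifiers()
    names = list(cfg.stratifiers) or list(all_strat)
    strat = {k: all_strat[k] for k in names if k in all_strat}
    table = stratified_estimates(
        cohort, strat,
        estimator_factory=lambda: _make_estimator(cfg, cfg.estimators[0], outcome, h),
        horizon=h, B=cfg.B, seed=cfg.seed,
    )
    table.to_csv(outdir / "subgroups.csv", index=False)
    (outdir / "subgroups.md").write_text(table.to_markdown(index=False))
    _manifest(outdir, cfg.__dict__, cfg.seed, {"stage": "subgroups", "outcome": outcome})
    return table


def plot_risk_curves(fitted: Mapping, path: str | Path) -> None:
    """Standardized survival curves, one panel per outcome (risk inset scale)."""
    outcomes = sorted({outcome for (_, outcome) in fitted})
    fig, axes = plt.subplots(1, max(len(outcomes), 1), figsize=(5.5 * max(len(outcomes), 1), 4.2))
    axes = np.atleast_1d(axes)
    labels = {1: "thrombus aspiration", 0: "no thrombus aspiration"}
    for ax, outcome in zip(axes, outcomes):
        for (estimator, oc), est in fitted.items():
            if oc != outcome:
                continue
            for arm in (0, 1):
                curve = est.predict_risk(arm)
                k = np.arange(0, curve.horizon + 1)
                surv = np.concatenate([[1.0], curve.survival])
                style = "-" if arm == 1 else "--"
                ax.step(k, surv, style, where="post",
                        label=f"{labels[arm]} ({estimator})")
        ax.set_xlabel("months since PCI")
        ax.set_ylabel("survival probability" if outcome == "death" else "event-free probability")
        ax.set_title({"death": "Death", "mi": "Myocardial infarction"}.get(outcome, outcome))
        ax.legend(loc="lower left", fontsize=8)
        ax.set_ylim(bottom=None, top=1.001)
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)
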