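"""Risk curves and effect contrasts.

A :class:`RiskCurve` stores the standardized cumulative risk of one treatment
strategy on the discrete follow-up grid; :func:`contrast` turns a pair of
curves into an absolute (risk difference, percentage points) and relative
(risk ratio) effect at a chosen horizon.  Report formatting follows the
conventions of cardiology trial tables: risks and risk differences to one
decimal in percent, risk ratios to two decimals.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["RiskCurve", "EffectEstimate", "contrast"]

_MONOTONE_TOL = 1e-10


@dataclass
class RiskCurve:
    """Cumulative risk R_k for intervals k = 1..K under one strategy."""

    strategy: int
    risks: np.ndarray
    estimator: str  # "gformula" | "ipw" | "kaplan-meier" | "plugin"
    outcome: str = ""

    def __post_init__(self) -> None:
        r = np.asarray(self.risks, dtype=float)
        if r.ndim != 1 or len(r) == 0:
            raise ValueError("risks must be a non-empty 1-d array")
        if np.any(r < -_MONOTONE_TOL) or np.any(r > 1.0 + _MONOTONE_TOL):
            raise ValueError("cumulative risks must lie in [0, 1]")
        if np.any(np.diff(r) < -_MONOTONE_TOL):
            raise ValueError("cumulative risk curve must be non-decreasing")
        self.risks = np.clip(r, 0.0, 1.0)

    @property
    def horizon(self) -> int:
        return len(self.risks)

    def risk_at(self, k: int) -> float:
        if not 1 <= k <= self.horizon:
            raise ValueError(f"interval {k} outside 1..{self.horizon}")
        return float(self.risks[k - 1])

    @property
    def survival(self) -> np.ndarray:
        return 1.0 - self.risks


@dataclass
class EffectEstimate:
    """Risk difference (percentage points) and risk ratio at one horizon.

    ``rd_ci``/``rr_ci``/``risk1_ci``/``risk0_ci`` are optional 95% bootstrap
    bounds; ``rr`` is NaN with ``rr_defined=False`` when the reference risk
    is zero.
    """

    outcome: str
    horizon: int
    risk1: float
    risk0: float
    rd: float  # percentage points
    rr: float
    estimator: str
    label: str = "main"
    rd_ci: tuple[float, float] | None = None
    rr_ci: tuple[float, float] | None = None
    risk1_ci: tuple[float, float] | None = None
    risk0_ci: tuple[float, float] | None = None
    rr_defined: bool = True

    def __post_init__(self) -> None:
        for ci, point in (
            (self.rd_ci, self.rd),
            (self.rr_ci, self.rr),
            (self.risk1_ci, self.risk1),
            (self.risk0_ci, self.risk0),
        ):
            if ci is not None:
                lo, hi = ci
                if not lo <= hi:
                    raise ValueError(f"CI bounds out of order: {ci}")

    def formatted(self) -> dict[str, object]:
        """Table-style rounding: risks/RD one decimal in %, RR two decimals."""
        out: dict[str, object] = {
            "outcome": self.outcome,
            "horizon": self.horizon,
            "estimator": self.estimator,
            "label": self.label,
            "risk1_pct": round(100.0 * self.risk1, 1),
            "risk0_pct": round(100.0 * self.risk0, 1),
            "rd_pp": round(self.rd, 1),
            "rr": round(self.rr, 2) if self.rr_defined else None,
        }
        if self.rd_ci is not None:
            out["rd_ci"] = (round(self.rd_ci[0], 1), round(self.rd_ci[1], 1))
        if self.rr_ci is not None:
            out["rr_ci"] = (round(self.rr_ci[0], 2), round(self.rr_ci[1], 2))
        return out

    def to_dict(self) -> dict[str, object]:
        d = {
            "outcome": self.outcome,
            "horizon": self.horizon,
            "estimator": self.estimator,
            "label": self.label,
            "risk1": self.risk1,
            "risk0": self.risk0,
            "rd": self.rd,
            "rr": self.rr if self.rr_defined else None,
        }
        for name in ("rd_ci", "rr_ci", "risk1_ci", "risk0_ci"):
            ci = getattr(self, name)
            if ci is not None:
                d[name] = list(ci)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def contrast(
    curve1: RiskCurve, curve0: RiskCurve, horizon: int, label: str = "main"
) -> EffectEstimate:
    """Risk difference and ratio comparing ``curve1`` against ``curve0``.

    The curves must come from the same estimator on the same grid.  RD is in
    percentage points (risk difference of 0.007 reports as 0.7).
    """
    if curve1.estimator != curve0.estimator:
        raise ValueError(
            f"cannot contrast curves from different estimators "
            f"({curve1.estimator!r} vs {curve0.estimator!r})"
        )
    if curve1.horizon != curve0.horizon:
        raise ValueError("curves have different follow-up grids")
    if not 1 <= horizon <= curve1.horizon:
        raise ValueError(f"horizon {horizon} beyond curve length {curve1.horizon}")
    r1 = curve1.risk_at(horizon)
    r0 = curve0.risk_at(horizon)
    rd = 100.0 * (r1 - r0)
    if r0 == 0.0 and r1 > 0.0:
        warnings.warn("reference risk is 0; risk ratio undefined", stacklevel=2)
        rr, defined = float("nan"), False
    elif r0 == 0.0:
        rr, defined = 1.0, True  # 0/0: identical degenerate curves
    else:
        rr, defined = r1 / r0, True
    return EffectEstimate(
        outcome=curve1.outcome or curve0.outcome,
        horizon=horizon,
        risk1=r1,
        risk0=r0,
        rd=rd,
        rr=rr,
        estimator=curve1.estimator,
        label=label,
        rr_defined=defined,
    )
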