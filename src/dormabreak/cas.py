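"""Stage-wise models of sprouting percentage against chilling accumulation.

For a fixed warming day ("bud stage", e.g. day 37, 40, 44 or 50), each
chilling treatment contributes one point (Ca, sprouting %), where Ca is
the chilling accumulation delivered by the constant-temperature
treatment.  A quadratic p(Ca) = alpha*Ca^2 + beta*Ca + gamma is fitted by
ordinary least squares; with alpha < 0 the vertex gives the optimum
chilling requirement at that stage, and the lower crossing of a target
percentage gives the smallest sufficient accumulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .chill import ChillUnitModel, chilling_accumulation, response_curves
from .datatypes import SproutingExperiment, TemperatureSchedule
from .errors import (
    NoOptimumError,
    UnachievableTargetError,
    UnderdeterminedError,
    ValidationError,
)


@dataclass(frozen=True)
class CASStageModel:
    """Fitted accumulation-to-sprouting model for one warming-day stage."""

    stage_day: int
    alpha: float  # Ca^2 coefficient
    beta: float  # Ca coefficient
    gamma: float  # intercept
    r_squared: float = float("nan")
    form: str = "quadratic"

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma"):
            if not math.isfinite(getattr(self, name)):
                raise ValidationError(f"coefficient {name} must be finite")

    @property
    def has_optimum(self) -> bool:
        return self.alpha < 0

    @property
    def optimum_ca(self) -> float:
        """Vertex abscissa: the optimum chilling requirement (Ca)."""
        if not self.has_optimum:
            raise NoOptimumError(
                f"stage-{self.stage_day} model opens upward: no optimum Ca"
            )
        return -self.beta / (2.0 * self.alpha)

    @property
    def maximum_pct(self) -> float:
        """Largest predicted sprouting percentage over Ca >= 0 (clamped)."""
        candidates = [self.gamma]
        if self.has_optimum and self.optimum_ca >= 0:
            candidates.append(self._poly(self.optimum_ca))
        if not self.has_optimum:
            return 100.0  # upward/linear: unbounded above, clamp dominates
        return float(min(100.0, max(candidates)))

    def _poly(self, ca):
        ca = np.asarray(ca, dtype=float)
        return self.alpha * ca**2 + self.beta * ca + self.gamma

    def predict(self, ca):
        """Predicted sprouting percentage at accumulation `ca`, in [0, 100]."""
        ca_arr = np.asarray(ca, dtype=float)
        if np.any(ca_arr < 0):
            raise ValidationError("chilling accumulation must be >= 0")
        out = np.clip(self._poly(ca_arr), 0.0, 100.0)
        if np.isscalar(ca) or np.ndim(ca) == 0:
            return float(out)
        return out

    def coefficients(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.gamma)

    def summary(self) -> str:
        lines = [
            f"CAS stage model, warming day {self.stage_day}",
            f"  p(Ca) = {self.alpha:+.6g}*Ca^2 {self.beta:+.6g}*Ca {self.gamma:+.6g}",
        ]
        if self.has_optimum:
            lines.append(f"  optimum Ca          : {self.optimum_ca:9.1f} Ca")
            lines.append(f"  maximum sprouting   : {self.maximum_pct:9.2f} %")
        else:
            lines.append("  no interior optimum (alpha >= 0)")
        if math.isfinite(self.r_squared):
            lines.append(f"  R-squared           : {self.r_squared:9.4f}")
        return "\n".join(lines)

    def plot(self, points: pd.DataFrame | None = None, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        hi = points["ca"].max() if points is not None else (
            2 * self.optimum_ca if self.has_optimum else 2500.0
        )
        grid = np.linspace(0, hi, 300)
        ax.plot(grid, self.predict(grid), label=f"day {self.stage_day} fit")
        if points is not None:
            ax.scatter(points["ca"], points["sprouting_pct"], color="k", s=12)
        ax.set_xlabel("chilling accumulation (Ca)")
        ax.set_ylabel("sprouting (%)")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# Observations and fitting
# ---------------------------------------------------------------------------

def stage_observations(
    experiment: SproutingExperiment, model: ChillUnitModel, stage_day: int
) -> pd.DataFrame:
    """One (Ca, sprouting %) point per chilling treatment at `stage_day`.

    Treatments at temperatures with zero chill unit (no dormancy-release
    effect) are excluded: they deliver no accumulation regardless of
    duration.
    """
    if not 1 <= stage_day <= experiment.n_days:
        raise ValidationError(
            f"stage_day {stage_day} outside recorded warming days "
            f"1..{experiment.n_days}"
        )
    rows = []
    for curve in response_curves(experiment):
        cu = model.cu_value(curve.temperature)
        if cu <= 0:
            continue
        schedule = TemperatureSchedule.constant(curve.temperature, curve.chilling_days)
        ca = chilling_accumulation(model, schedule)
        rows.append(
            (
                curve.temperature,
                curve.chilling_days,
                ca,
                float(curve.sprouting_pct[stage_day - 1]),
            )
        )
    return pd.DataFrame(
        rows, columns=["temperature", "chilling_days", "ca", "sprouting_pct"]
    )


class CASRegression:
    """OLS regression of sprouting percentage on chilling accumulation."""

    def __init__(self, ca: Sequence[float], sprouting_pct: Sequence[float], stage_day: int):
        self.ca = np.asarray(ca, dtype=float)
        self.sprouting_pct = np.asarray(sprouting_pct, dtype=float)
        self.stage_day = int(stage_day)
        if self.ca.size != self.sprouting_pct.size:
            raise ValidationError("ca and sprouting_pct differ in length")

    @classmethod
    def from_points(cls, points: pd.DataFrame, stage_day: int) -> "CASRegression":
        return cls(points["ca"], points["sprouting_pct"], stage_day)

    def fit(self, form: str = "quadratic") -> CASStageModel:
        if form != "quadratic":
            raise ValidationError(f"unsupported CAS form: {form!r}")
        if np.unique(self.ca).size < 3:
            raise UnderdeterminedError(
                "need >= 3 distinct accumulation values for a quadratic fit"
            )
        x = self.ca
        design = np.column_stack([np.ones_like(x), x, x**2])
        res = sm.OLS(self.sprouting_pct, design).fit()
        gamma, beta, alpha = res.params
        return CASStageModel(
            stage_day=self.stage_day,
            alpha=float(alpha),
            beta=float(beta),
            gamma=float(gamma),
            r_squared=float(res.rsquared),
            form=form,
        )


def fit_cas(points: pd.DataFrame, stage_day: int, form: str = "quadratic") -> CASStageModel:
    """Fit a stage model to (Ca, sprouting %) points (see CASRegression)."""
    return CASRegression.from_points(points, stage_day).fit(form=form)


def predict_sprouting(cas: CASStageModel, ca) -> float:
    return cas.predict(ca)


def optimum_ca(cas: CASStageModel) -> float:
    return cas.optimum_ca


def required_ca(cas: CASStageModel, target_pct: float) -> float:
    """Smallest accumulation achieving at least `target_pct` sprouting.

    For a concave quadratic this is the lower crossing of the target
    level (the agronomically meaningful "smallest sufficient chilling").
    """
    if not 0 <= target_pct <= 100:
        raise ValidationError("target percentage must lie in [0, 100]")
    if cas.predict(0.0) >= target_pct:
        return 0.0
    if cas.alpha == 0:
        if cas.beta <= 0:
            raise UnachievableTargetError(
                f"target {target_pct}% unachievable; model maximum is "
                f"{cas.maximum_pct:.2f}%"
            )
        return float((target_pct - cas.gamma) / cas.beta)
    disc = cas.beta**2 - 4.0 * cas.alpha * (cas.gamma - target_pct)
    if cas.has_optimum:
        if cas._poly(max(cas.optimum_ca, 0.0)) < target_pct - 1e-9:
            raise UnachievableTargetError(
                f"target {target_pct}% exceeds the stage-{cas.stage_day} model "
                f"maximum of {cas.maximum_pct:.2f}%"
            )
        roots = np.sort(np.roots([cas.alpha, cas.beta, cas.gamma - target_pct]).real)
        lo, hi = roots
        return float(max(lo, 0.0))
    # alpha > 0: polynomial is unbounded above; the target is reached at the
    # first non-negative crossing into the >= target region.
    roots = np.sort(np.roots([cas.alpha, cas.beta, cas.gamma - target_pct]).real) if disc >= 0 else np.array([])
    candidates = [r for r in roots if r >= 0 and cas._poly(r + 1e-9) >= target_pct - 1e-9]
    if candidates:
        return float(candidates[0])
    raise UnachievableTargetError(
        f"target {target_pct}% not reachable at non-negative accumulation"
    )


# ---------------------------------------------------------------------------
# Verification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VerificationStats:
    """Agreement between observed and model-predicted sprouting values."""

    r_squared: float  # squared Pearson correlation
    slope: float  # OLS slope of observed on predicted
    intercept: float
    bias: float  # mean(observed - predicted)
    n: int

    def summary(self) -> str:
        return (
            f"verification on n={self.n} points: R^2={self.r_squared:.4f}, "
            f"observed = {self.slope:.3f} x predicted + {self.intercept:.2f}, "
            f"mean bias {self.bias:+.2f} %"
        )


def verify_predictions(predicted: Sequence[float], observed: Sequence[float]) -> VerificationStats:
    """Compare predictions with observations (observed regressed on predicted)."""
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.size != obs.size:
        raise ValidationError(
            f"predicted ({pred.size}) and observed ({obs.size}) differ in length"
        )
    if pred.size < 3:
        raise ValidationError("need at least 3 points for verification")
    if np.allclose(pred, pred[0]) or np.allclose(obs, obs[0]):
        r2 = 1.0 if np.allclose(obs - pred, obs[0] - pred[0]) else 0.0
        slope = 1.0 if np.allclose(obs - pred, obs[0] - pred[0]) else 0.0
        intercept = float(np.mean(obs) - slope * np.mean(pred))
    else:
        r = float(np.corrcoef(pred, obs)[0, 1])
        r2 = r**2
        slope = float(np.cov(pred, obs, ddof=1)[0, 1] / np.var(pred, ddof=1))
        intercept = float(np.mean(obs) - slope * np.mean(pred))
    return VerificationStats(
        r_squared=r2,
        slope=slope,
        intercept=intercept,
        bias=float(np.mean(obs - pred)),
        n=int(pred.size),
    )
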