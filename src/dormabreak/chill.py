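"""Chill-unit estimation and the quadratic chill-unit model.

The chill unit (CU) of a temperature is the relative efficiency of one
hour at that temperature for releasing rhizome-bud dormancy, defined as
the mean rising-phase slope of the sprouting curves observed after
chilling at that temperature, divided by the same quantity at the
reference temperature (0 degC).  A concave quadratic CU(T) = aT^2 + bT + c
is fitted to the per-temperature chill units; its vertex gives the
optimum chilling temperature and its larger root the upper temperature
limit beyond which chilling is ineffective.

Chilling accumulation (Ca, in CU-hours) over an arbitrary
piecewise-constant temperature schedule is the sum over segments of
CU(T) x hours, with CU clamped to zero outside the model's valid range.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import statsmodels.api as sm

from .datatypes import (
    ChillResponseCurve,
    ChillUnitTable,
    Segment,
    SproutingExperiment,
    TemperatureSchedule,
)
from .errors import NoOptimumError, UnderdeterminedError, ValidationError


# ---------------------------------------------------------------------------
# Results object
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChillUnitModel:
    """Fitted (or externally supplied) quadratic chill-unit model.

    CU(T) = a T^2 + b T + c with a < 0, valid on [0, t_upper]; outside the
    valid range, and wherever the polynomial is negative, the chill unit
    is zero.
    """

    a: float
    b: float
    c: float
    r_squared: float = float("nan")

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if not math.isfinite(getattr(self, name)):
                raise ValidationError(f"coefficient {name} must be finite")
        if self.a >= 0:
            raise NoOptimumError(
                "quadratic opens upward (a >= 0): no interior optimum; "
                "the chill-unit model class requires a concave response"
            )

    # -- derived constants ---------------------------------------------------
    @property
    def t_opt(self) -> float:
        """Optimum chilling temperature (vertex abscissa), degC."""
        return -self.b / (2.0 * self.a)

    @property
    def cu_max(self) -> float:
        """Chill unit at the optimum temperature (vertex ordinate)."""
        return self.c - self.b**2 / (4.0 * self.a)

    @property
    def t_upper(self) -> float:
        """Upper temperature limit: larger real root of the quadratic, degC."""
        disc = self.b**2 - 4.0 * self.a * self.c
        if disc < 0:
            raise NoOptimumError("quadratic has no real roots; no upper limit")
        # a < 0, so the larger root is (-b - sqrt(disc)) / (2a)
        return (-self.b - math.sqrt(disc)) / (2.0 * self.a)

    @property
    def valid_range(self) -> tuple[float, float]:
        return (0.0, self.t_upper)

    # -- evaluation ------------------------------------------------------------
    def cu_value(self, temperature):
        """Chill unit at `temperature` (scalar or array), clamped to >= 0.

        Temperatures below 0 degC are outside the model's domain and
        contribute nothing (a warning is emitted); so do temperatures at
        or above the upper limit.
        """
        t = np.asarray(temperature, dtype=float)
        if np.any(t < 0):
            warnings.warn(
                "temperatures below 0 degC are outside the chill-unit model's "
                "domain and contribute 0 CU",
                stacklevel=2,
            )
        poly = self.a * t**2 + self.b * t + self.c
        out = np.where((t < 0) | (t > self.t_upper) | (poly < 0), 0.0, poly)
        if np.isscalar(temperature) or np.ndim(temperature) == 0:
            return float(out)
        return out

    predict = cu_value

    def coefficients(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    def summary(self) -> str:
        lines = [
            "Quadratic chill-unit model  CU(T) = a*T^2 + b*T + c",
            f"  a = {self.a:+.6g}   b = {self.b:+.6g}   c = {self.c:+.6g}",
            f"  optimum temperature : {self.t_opt:7.2f} degC",
            f"  maximum chill unit  : {self.cu_max:7.4f} CU",
            f"  upper limit         : {self.t_upper:7.2f} degC",
        ]
        if math.isfinite(self.r_squared):
            lines.append(f"  R-squared           : {self.r_squared:7.4f}")
        return "\n".join(lines)

    def plot(self, table: ChillUnitTable | None = None, ax=None):
        """Plot the fitted curve (and, optionally, the chill-unit table)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        grid = np.linspace(0, self.t_upper, 200)
        ax.plot(grid, self.cu_value(grid), label="fitted CU(T)")
        if table is not None:
            ax.scatter(table.temperature, table.chill_unit, color="k", label="chill units")
        ax.set_xlabel("chilling temperature (degC)")
        ax.set_ylabel("chill unit (CU)")
        ax.legend()
        return ax


def optimum_temperature(model: ChillUnitModel) -> float:
    return model.t_opt


def cu_max(model: ChillUnitModel) -> float:
    return model.cu_max


def upper_limit(model: ChillUnitModel) -> float:
    return model.t_upper


def cu_value(model: ChillUnitModel, temperature) -> float:
    return model.cu_value(temperature)


# ---------------------------------------------------------------------------
# From sprouting curves to chill units
# ---------------------------------------------------------------------------

def response_curves(experiment: SproutingExperiment) -> list[ChillResponseCurve]:
    """Replicate-mean cumulative sprouting percentage per treatment."""
    curves = []
    for temperature, chilling_days in experiment.treatments():
        reps = experiment.replicates(temperature, chilling_days)
        pct = np.mean([r.sprouting_pct() for r in reps], axis=0)
        curves.append(
            ChillResponseCurve(
                temperature=temperature,
                chilling_days=chilling_days,
                sprouting_pct=pct,
            )
        )
    return curves


class CurveSlope(NamedTuple):
    slope: float  # percent per warming day
    no_emergence: bool


def curve_slope(curve: ChillResponseCurve) -> CurveSlope:
    """Rising-phase slope of a sprouting curve, in % per warming day.

    The slope is the ordinary-least-squares slope of sprouting percentage
    against warming day, restricted to the rising window [first day with a
    positive value, first day reaching the curve's maximum].  A curve that
    never leaves zero has slope 0 and is flagged ``no_emergence`` (the
    supra-threshold temperatures in the source experiments never emerge).
    """
    v = curve.sprouting_pct
    if v.max() <= 0:
        return CurveSlope(0.0, True)
    start = int(np.argmax(v > 0))
    end = int(np.argmax(v >= v.max()))
    if end == start:
        # Single-day jump: use the last pre-emergence day as the left
        # anchor so a two-point slope is defined.
        start = max(start - 1, 0)
    if end == start:  # jump on day 1 of a curve; treat rise as one day
        return CurveSlope(float(v[end]), False)
    days = curve.days[start : end + 1].astype(float)
    vals = v[start : end + 1]
    slope = float(np.polyfit(days, vals, 1)[0])
    return CurveSlope(slope, False)


def chill_unit_table(
    experiment: SproutingExperiment, reference_temperature: float = 0.0
) -> ChillUnitTable:
    """Per-temperature chill units relative to the reference temperature.

    The mean slope at a temperature is the unweighted mean of the
    rising-phase slopes over all chilling durations applied at that
    temperature; the chill unit is the ratio to the reference
    temperature's mean slope.
    """
    temps = experiment.temperatures()
    if not any(np.isclose(t, reference_temperature) for t in temps):
        raise ValidationError(
            f"reference temperature {reference_temperature} degC not present "
            f"in experiment (temperatures: {temps})"
        )
    curves = response_curves(experiment)
    mean_slopes = []
    flags = []
    for t in temps:
        slopes = [curve_slope(c) for c in curves if c.temperature == t]
        mean_slopes.append(float(np.mean([s.slope for s in slopes])))
        flags.append(all(s.no_emergence for s in slopes))
    mean_slopes = np.asarray(mean_slopes)
    ref_idx = int(np.argmin(np.abs(np.asarray(temps) - reference_temperature)))
    ref_slope = mean_slopes[ref_idx]
    if ref_slope <= 0:
        raise ValidationError(
            f"reference temperature {reference_temperature} degC shows no "
            "emergence; chill units are undefined"
        )
    cu = mean_slopes / ref_slope
    cu[ref_idx] = 1.0  # exact by definition
    cu = np.clip(cu, 0.0, None)
    return ChillUnitTable(
        temperature=np.asarray(temps, dtype=float),
        mean_slope=mean_slopes,
        chill_unit=cu,
        reference_temperature=reference_temperature,
        no_emergence=np.asarray(flags),
    )


# ---------------------------------------------------------------------------
# Model fitting (statsmodels-style: model object -> fit() -> results)
# ---------------------------------------------------------------------------

class QuadraticChillModel:
    """OLS quadratic regression of chill unit on chilling temperature."""

    def __init__(self, temperature: Sequence[float], chill_unit: Sequence[float]):
        self.temperature = np.asarray(temperature, dtype=float)
        self.chill_unit = np.asarray(chill_unit, dtype=float)
        if self.temperature.size != self.chill_unit.size:
            raise ValidationError("temperature and chill_unit differ in length")
        if np.unique(self.temperature).size < 3:
            raise UnderdeterminedError(
                "need >= 3 distinct temperatures to fit a quadratic"
            )

    @classmethod
    def from_table(cls, table: ChillUnitTable) -> "QuadraticChillModel":
        return cls(table.temperature, table.chill_unit)

    def fit(self) -> ChillUnitModel:
        x = self.temperature
        design = np.column_stack([np.ones_like(x), x, x**2])
        res = sm.OLS(self.chill_unit, design).fit()
        c, b, a = res.params
        if a >= 0:
            raise NoOptimumError(
                "fitted quadratic opens upward: no interior optimum "
                "(chill-unit data are not concave in temperature)"
            )
        return ChillUnitModel(a=float(a), b=float(b), c=float(c), r_squared=float(res.rsquared))


def fit_cu_model(table: ChillUnitTable) -> ChillUnitModel:
    """Fit the quadratic chill-unit model to a chill-unit table."""
    return QuadraticChillModel.from_table(table).fit()


# ---------------------------------------------------------------------------
# Chilling accumulation over temperature schedules
# ---------------------------------------------------------------------------

def chilling_accumulation(model: ChillUnitModel, schedule: TemperatureSchedule) -> float:
    """Total chilling accumulation (Ca = CU x hours) over a schedule."""
    total = 0.0
    for seg in schedule.segments:
        total += model.cu_value(seg.temperature) * seg.hours
    return total


def ramp_schedule(
    start: float, end: float, step: float = 1.0, hold_days: float = 0.0
) -> TemperatureSchedule:
    """Daily temperature ramp followed by a hold at the final temperature.

    One 24-hour segment per ramp day at start, start+step, ..., end
    (inclusive), then a single hold segment of ``hold_days`` days at
    ``end``.
    """
    if step <= 0:
        raise ValidationError("step must be > 0")
    if end < start:
        raise ValidationError("end must be >= start")
    segments: list[Segment] = []
    if end > start:
        n_steps = int(round((end - start) / step))
        segments = [Segment(24.0, start + i * step) for i in range(n_steps + 1)]
    if hold_days > 0:
        segments.append(Segment(24.0 * hold_days, end))
    return TemperatureSchedule(segments)
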