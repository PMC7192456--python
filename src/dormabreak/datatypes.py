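"""Shared domain types for the dormancy-release pipeline.

The experimental unit throughout is a tray of rhizome buds chilled at one
temperature for one duration, then moved to warm conditions where the
cumulative number of sprouted buds is recorded daily (day 1 = first warm
day).  Expression data enter as an FPKM matrix (genes x samples) with one
quantitative trait value (sprouting percentage) per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, ValidationError


# ---------------------------------------------------------------------------
# Sprouting time courses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SproutingRecord:
    """One replicate tray: cumulative sprouted counts per warming day."""

    temperature: float
    chilling_days: float
    replicate: int
    n_buds: int
    sprouted_by_day: np.ndarray  # cumulative counts, index 0 == warming day 1

    def __post_init__(self) -> None:
        counts = np.asarray(self.sprouted_by_day, dtype=int)
        object.__setattr__(self, "sprouted_by_day", counts)
        object.__setattr__(self, "temperature", float(self.temperature))
        object.__setattr__(self, "chilling_days", float(self.chilling_days))
        object.__setattr__(self, "replicate", int(self.replicate))
        object.__setattr__(self, "n_buds", int(self.n_buds))
        if self.n_buds <= 0:
            raise ValidationError(f"n_buds must be positive, got {self.n_buds}")
        if self.chilling_days < 0:
            raise ValidationError(
                f"chilling_days must be >= 0, got {self.chilling_days}"
            )
        if counts.size == 0:
            raise ValidationError("sprouted_by_day must not be empty")
        if counts.min() < 0 or counts.max() > self.n_buds:
            raise ValidationError(
                f"counts must lie in [0, n_buds={self.n_buds}] for treatment "
                f"{self.temperature}degC x {self.chilling_days}d "
                f"rep {self.replicate}"
            )
        if np.any(np.diff(counts) < 0):
            day = int(np.where(np.diff(counts) < 0)[0][0]) + 2
            raise ValidationError(
                f"cumulative counts decrease at warming day {day} for "
                f"{self.temperature}degC x {self.chilling_days}d "
                f"rep {self.replicate}"
            )

    @property
    def n_days(self) -> int:
        return int(self.sprouted_by_day.size)

    def sprouting_pct(self) -> np.ndarray:
        """Cumulative sprouting percentage (exact ratio, not rounded)."""
        return 100.0 * self.sprouted_by_day / self.n_buds


@dataclass(frozen=True)
class SproutingExperiment:
    """A replicated chilling experiment: many trays across (T, duration)."""

    records: tuple[SproutingRecord, ...]

    def __init__(self, records: Iterable[SproutingRecord]):
        object.__setattr__(self, "records", tuple(records))
        if not self.records:
            raise ValidationError("experiment has no records")
        lengths = {r.n_days for r in self.records}
        if len(lengths) > 1:
            raise ValidationError(
                f"records have inconsistent day ranges: {sorted(lengths)}"
            )

    @property
    def n_days(self) -> int:
        return self.records[0].n_days

    def treatments(self) -> list[tuple[float, float]]:
        """Distinct (temperature, chilling_days) pairs, sorted."""
        return sorted({(r.temperature, r.chilling_days) for r in self.records})

    def temperatures(self) -> list[float]:
        return sorted({r.temperature for r in self.records})

    def replicates(self, temperature: float, chilling_days: float) -> list[SproutingRecord]:
        recs = [
            r
            for r in self.records
            if r.temperature == temperature and r.chilling_days == chilling_days
        ]
        if not recs:
            raise KeyError(
                f"no replicates for treatment {temperature}degC x {chilling_days}d"
            )
        return recs

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (record, warming day)."""
        rows = []
        for r in self.records:
            for day, count in enumerate(r.sprouted_by_day, start=1):
                rows.append(
                    (r.temperature, r.chilling_days, r.replicate, r.n_buds, day, int(count))
                )
        return pd.DataFrame(
            rows,
            columns=["temperature", "chilling_days", "replicate", "n_buds", "day", "sprouted"],
        )


@dataclass(frozen=True)
class ChillResponseCurve:
    """Replicate-mean cumulative sprouting percentage per warming day."""

    temperature: float
    chilling_days: float
    sprouting_pct: np.ndarray  # percent, index 0 == warming day 1

    def __post_init__(self) -> None:
        pct = np.asarray(self.sprouting_pct, dtype=float)
        object.__setattr__(self, "sprouting_pct", pct)
        if pct.min() < -1e-9 or pct.max() > 100 + 1e-9:
            raise ValidationError("sprouting percentages must lie in [0, 100]")
        if np.any(np.diff(pct) < -1e-9):
            raise ValidationError("sprouting percentage must be non-decreasing")

    @property
    def days(self) -> np.ndarray:
        return np.arange(1, self.sprouting_pct.size + 1)


@dataclass(frozen=True)
class ChillUnitTable:
    """Per-temperature mean rising-phase slope and relative chill unit.

    Chill units are dimensionless: the mean slope at each temperature
    divided by the mean slope at the reference temperature (0 degC in the
    source experiments), so the reference row is exactly 1.
    """

    temperature: np.ndarray
    mean_slope: np.ndarray  # percent / warming day
    chill_unit: np.ndarray  # relative to reference temperature
    reference_temperature: float
    no_emergence: np.ndarray = field(default=None)  # bool per row

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, dtype=float)
        s = np.asarray(self.mean_slope, dtype=float)
        cu = np.asarray(self.chill_unit, dtype=float)
        flags = (
            np.zeros(t.size, dtype=bool)
            if self.no_emergence is None
            else np.asarray(self.no_emergence, dtype=bool)
        )
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "mean_slope", s)
        object.__setattr__(self, "chill_unit", cu)
        object.__setattr__(self, "no_emergence", flags)
        if not (t.size == s.size == cu.size == flags.size):
            raise ValidationError("chill unit table columns differ in length")
        if np.any(cu < 0):
            raise ValidationError("chill units must be non-negative")
        ref = np.isclose(t, self.reference_temperature)
        if not ref.any():
            raise ValidationError(
                f"reference temperature {self.reference_temperature} not in table"
            )
        if not np.isclose(cu[ref][0], 1.0):
            raise ValidationError("reference chill unit must be exactly 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "temperature": self.temperature,
                "mean_slope": self.mean_slope,
                "chill_unit": self.chill_unit,
                "no_emergence": self.no_emergence,
            }
        )


# ---------------------------------------------------------------------------
# Temperature schedules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Segment:
    hours: float
    temperature: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "hours", float(self.hours))
        object.__setattr__(self, "temperature", float(self.temperature))
        if self.hours <= 0:
            raise ValidationError(f"segment duration must be > 0 h, got {self.hours}")


@dataclass(frozen=True)
class TemperatureSchedule:
    """Ordered piecewise-constant temperature program (durations in hours)."""

    segments: tuple[Segment, ...]

    def __init__(self, segments: Iterable[Segment | tuple[float, float]] = ()):
        segs = tuple(
            s if isinstance(s, Segment) else Segment(float(s[0]), float(s[1]))
            for s in segments
        )
        object.__setattr__(self, "segments", segs)

    @classmethod
    def constant(cls, temperature: float, days: float) -> "TemperatureSchedule":
        """A single segment held for `days` days (24 h per day)."""
        if days == 0:
            return cls(())
        return cls([Segment(24.0 * days, temperature)])

    @property
    def total_hours(self) -> float:
        return float(sum(s.hours for s in self.segments))

    def __add__(self, other: "TemperatureSchedule") -> "TemperatureSchedule":
        return TemperatureSchedule(self.segments + other.segments)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.hours, s.temperature) for s in self.segments],
            columns=["hours", "temperature"],
        )


# ---------------------------------------------------------------------------
# Expression data
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionMatrix:
    """FPKM expression matrix (genes x samples) with one trait per sample."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray  # shape (n_genes, n_samples), FPKM >= 0
    trait: np.ndarray  # sprouting percentage, length n_samples

    def __init__(
        self,
        gene_ids: Sequence[str],
        sample_ids: Sequence[str],
        values: np.ndarray,
        trait: Sequence[float],
    ):
        genes = tuple(str(g) for g in gene_ids)
        samples = tuple(str(s) for s in sample_ids)
        vals = np.asarray(values, dtype=float)
        tr = np.asarray(trait, dtype=float)
        if len(set(genes)) != len(genes):
            raise ValidationError("duplicate gene ids")
        if vals.shape != (len(genes), len(samples)):
            raise ValidationError(
                f"values shape {vals.shape} does not match "
                f"{len(genes)} genes x {len(samples)} samples"
            )
        if tr.shape != (len(samples),):
            raise AlignmentError(
                f"trait length {tr.size} does not match {len(samples)} samples"
            )
        if np.any(vals < 0):
            raise ValidationError("FPKM values must be non-negative")
        if not np.all(np.isfinite(vals)):
            raise ValidationError("FPKM values must be finite")
        object.__setattr__(self, "gene_ids", genes)
        object.__setattr__(self, "sample_ids", samples)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "trait", tr)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def zero_variance_genes(self) -> list[str]:
        """Genes constant across samples (excluded from correlation work)."""
        sd = self.values.std(axis=1)
        return [g for g, s in zip(self.gene_ids, sd) if s == 0.0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    def trait_series(self) -> pd.Series:
        return pd.Series(self.trait, index=list(self.sample_ids), name="sprouting_percentage")


@dataclass(frozen=True)
class ModuleAssignment:
    """Coexpression module labels plus eigengene/trait statistics.

    ``labels`` partitions all analysed genes; the label ``"unassigned"``
    marks genes that fell below the minimum module size.  Eigengenes are
    unit-norm per-sample scores oriented so the mean correlation with
    member genes is non-negative.
    """

    labels: pd.Series  # gene -> module name
    eigengenes: pd.DataFrame  # modules x samples, unit Euclidean norm rows
    module_trait_cor: pd.Series  # module -> Pearson r with trait
    module_trait_p: pd.Series
    gene_stats: pd.DataFrame  # per gene: module, gs, mm, p_gs, p_mm

    UNASSIGNED = "unassigned"

    def modules(self) -> list[str]:
        """Module names, excluding the unassigned bucket."""
        return [m for m in self.eigengenes.index]

    def module_genes(self, module: str) -> list[str]:
        if module not in set(self.labels.values):
            raise KeyError(f"unknown module: {module}")
        return sorted(self.labels.index[self.labels == module])


@dataclass(frozen=True)
class HubCriteria:
    """Thresholds for the real-hub-gene screen.

    ``edge_weight_threshold`` maps module name -> minimum (strict) edge
    weight for the module's network; GS/MM thresholds are inclusive.
    """

    edge_weight_threshold: Mapping[str, float] = field(default_factory=dict)
    default_edge_weight_threshold: float = 0.2
    kmeans_k: int = 3
    gs_min: float = 0.95
    mm_min: float = 0.98
    module_trait_min: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        for mod, thr in self.edge_weight_threshold.items():
            if not 0.0 <= thr <= 1.0:
                raise ValidationError(
                    f"edge weight threshold for {mod} must lie in [0, 1]"
                )
        for name in ("default_edge_weight_threshold", "gs_min", "mm_min", "module_trait_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.kmeans_k < 2:
            raise ValidationError("kmeans_k must be >= 2")

    def threshold_for(self, module: str) -> float:
        return float(
            self.edge_weight_threshold.get(module, self.default_edge_weight_threshold)
        )
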