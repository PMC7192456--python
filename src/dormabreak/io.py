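"""Readers and writers for the pipeline's plain-text formats.

Formats
-------
sprouting CSV (long format)
    columns: temperature, chilling_days, replicate, n_buds, day, sprouted
    (`sprouted` is the cumulative count by warming day `day`, 1-based)
expression CSV
    first column gene_id, remaining columns sample ids, values FPKM
trait CSV
    columns: sample_id, sprouting_percentage
model JSON
    {"type", "coefficients": {...}, "derived": {...}, "fit": {"r_squared"}}
schedule CSV
    columns: hours, temperature
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cas import CASStageModel
from .chill import ChillUnitModel
from .datatypes import ExpressionMatrix, SproutingExperiment, SproutingRecord, TemperatureSchedule
from .errors import AlignmentError, IntegrityError, SchemaError, ValidationError

SPROUTING_COLUMNS = ["temperature", "chilling_days", "replicate", "n_buds", "day", "sprouted"]


# ---------------------------------------------------------------------------
# Sprouting experiments
# ---------------------------------------------------------------------------

def read_sprouting_csv(path) -> SproutingExperiment:
    """Load a long-format sprouting time-course table.

    Cumulative-count violations (decreasing counts, counts above n_buds)
    raise :class:`ValidationError` naming the offending treatment; they
    are never silently repaired.
    """
    df = pd.read_csv(path)
    missing = [c for c in SPROUTING_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"sprouting CSV {path} missing columns: {missing}")
    records = []
    for (t, dur, rep), grp in df.groupby(["temperature", "chilling_days", "replicate"], sort=True):
        grp = grp.sort_values("day")
        days = grp["day"].to_numpy()
        if days[0] != 1 or np.any(np.diff(days) != 1):
            raise ValidationError(
                f"warming days must be contiguous from 1 for treatment "
                f"{t}degC x {dur}d rep {rep}"
            )
        n_buds = grp["n_buds"].unique()
        if n_buds.size != 1:
            raise ValidationError(
                f"inconsistent n_buds within treatment {t}degC x {dur}d rep {rep}"
            )
        records.append(
            SproutingRecord(
                temperature=float(t),
                chilling_days=float(dur),
                replicate=int(rep),
                n_buds=int(n_buds[0]),
                sprouted_by_day=grp["sprouted"].to_numpy(),
            )
        )
    return SproutingExperiment(records)


def write_sprouting_csv(experiment: SproutingExperiment, path) -> None:
    experiment.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def read_expression_csv(path, trait_path) -> ExpressionMatrix:
    """Load an FPKM matrix plus per-sample trait, aligning sample order."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise SchemaError(f"expression CSV {path} needs gene_id + sample columns")
    gene_col = df.columns[0]
    df = df.set_index(gene_col)
    traits = pd.read_csv(trait_path)
    for col in ("sample_id", "sprouting_percentage"):
        if col not in traits.columns:
            raise SchemaError(f"trait CSV {trait_path} missing column {col!r}")
    traits = traits.set_index("sample_id")["sprouting_percentage"]
    expr_samples = list(df.columns)
    missing = sorted(set(expr_samples) - set(traits.index))
    extra = sorted(set(traits.index) - set(expr_samples))
    if missing or extra:
        raise AlignmentError(
            f"sample mismatch between expression and trait files: "
            f"missing from trait {missing}, extra in trait {extra}"
        )
    if (df.values < 0).any():
        raise ValidationError("negative FPKM values in expression matrix")
    return ExpressionMatrix(
        gene_ids=list(df.index.astype(str)),
        sample_ids=expr_samples,
        values=df.values.astype(float),
        trait=traits.loc[expr_samples].to_numpy(dtype=float),
    )


def write_expression_csv(expr: ExpressionMatrix, path, trait_path) -> None:
    frame = expr.to_frame()
    frame.index.name = "gene_id"
    frame.to_csv(path)
    pd.DataFrame(
        {"sample_id": list(expr.sample_ids), "sprouting_percentage": expr.trait}
    ).to_csv(trait_path, index=False)


# ---------------------------------------------------------------------------
# Model JSON
# ---------------------------------------------------------------------------

_REL_TOL = 1e-6


def write_model_json(model, path) -> None:
    """Serialize a chill-unit or CAS stage model with derived constants."""
    if isinstance(model, ChillUnitModel):
        payload = {
            "type": "chill_unit",
            "coefficients": {"a": model.a, "b": model.b, "c": model.c},
            "derived": {
                "t_opt": model.t_opt,
                "cu_max": model.cu_max,
                "t_upper": model.t_upper,
            },
            "fit": {"r_squared": model.r_squared},
        }
    elif isinstance(model, CASStageModel):
        payload = {
            "type": "cas_stage",
            "stage_day": model.stage_day,
            "form": model.form,
            "coefficients": {
                "alpha": model.alpha,
                "beta": model.beta,
                "gamma": model.gamma,
            },
            "derived": {
                "optimum_ca": model.optimum_ca if model.has_optimum else None,
                "maximum_pct": model.maximum_pct,
            },
            "fit": {"r_squared": model.r_squared},
        }
    else:
        raise ValidationError(f"cannot serialize model of type {type(model).__name__}")
    Path(path).write_text(json.dumps(payload, indent=2, allow_nan=True))


def _check(name: str, stored, recomputed) -> None:
    if stored is None and recomputed is None:
        return
    if stored is None or not np.isclose(stored, recomputed, rtol=_REL_TOL, atol=1e-9):
        raise IntegrityError(
            f"stored derived constant {name}={stored} disagrees with value "
            f"recomputed from coefficients ({recomputed})"
        )


def read_model_json(path):
    """Load a model, recomputing derived constants and checking integrity."""
    payload = json.loads(Path(path).read_text())
    kind = payload.get("type")
    coeffs = payload.get("coefficients", {})
    derived = payload.get("derived", {})
    r2 = payload.get("fit", {}).get("r_squared", float("nan"))
    r2 = float("nan") if r2 is None else float(r2)
    if kind == "chill_unit":
        model = ChillUnitModel(
            a=float(coeffs["a"]), b=float(coeffs["b"]), c=float(coeffs["c"]), r_squared=r2
        )
        _check("t_opt", derived.get("t_opt"), model.t_opt)
        _check("cu_max", derived.get("cu_max"), model.cu_max)
        _check("t_upper", derived.get("t_upper"), model.t_upper)
        return model
    if kind == "cas_stage":
        model = CASStageModel(
            stage_day=int(payload["stage_day"]),
            alpha=float(coeffs["alpha"]),
            beta=float(coeffs["beta"]),
            gamma=float(coeffs["gamma"]),
            r_squared=r2,
            form=payload.get("form", "quadratic"),
        )
        _check(
            "optimum_ca",
            derived.get("optimum_ca"),
            model.optimum_ca if model.has_optimum else None,
        )
        _check("maximum_pct", derived.get("maximum_pct"), model.maximum_pct)
        return model
    raise SchemaError(f"unknown model type in {path}: {kind!r}")


# ---------------------------------------------------------------------------
# Temperature schedules
# ---------------------------------------------------------------------------

def read_schedule_csv(path) -> TemperatureSchedule:
    df = pd.read_csv(path)
    for col in ("hours", "temperature"):
        if col not in df.columns:
            raise SchemaError(f"schedule CSV {path} missing column {col!r}")
    return TemperatureSchedule(list(zip(df["hours"], df["temperature"])))


def write_schedule_csv(schedule: TemperatureSchedule, path) -> None:
    schedule.to_frame().to_csv(path, index=False)
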