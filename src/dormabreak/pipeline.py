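"""End-to-end pipeline orchestration with provenance records.

Two workflows mirror the analysis: the chilling workflow (sprouting CSV
-> chill-unit table -> quadratic CU model -> stage-wise CAS models ->
optional verification against a second experiment) and the network
workflow (expression + trait CSV -> soft threshold -> TOM -> modules ->
eigengenes -> GS/MM -> real-hub screen -> edge lists).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cas import fit_cas, stage_observations, verify_predictions
from .chill import chill_unit_table, fit_cu_model
from .datatypes import HubCriteria
from .errors import ConfigError, DormabreakError
from .hubs import export_edges_tsv, module_edge_list, real_hub_genes
from .io import read_expression_csv, read_sprouting_csv, write_model_json
from .network import UNASSIGNED, WeightedCoexpressionNetwork

log = logging.getLogger("dormabreak")

DEFAULT_STAGES = (37, 40, 44, 50)


@dataclass
class PipelineConfig:
    """Paths and options for the two workflows; see module docstring."""

    # inputs
    sprouting_csv: str | None = None
    verification_csv: str | None = None
    expression_csv: str | None = None
    trait_csv: str | None = None
    out_dir: str = "dormabreak_out"
    # chilling options
    reference_temperature: float = 0.0
    stages: tuple[int, ...] = DEFAULT_STAGES
    cas_form: str = "quadratic"
    # network options
    powers: tuple[int, ...] = tuple(range(1, 21))
    beta: int | None = None
    min_module_size: int = 30
    merge_height: float = 0.8
    transform: str = "log1p"
    module_trait_min: float = 0.9
    edge_weight_threshold: dict = field(default_factory=dict)
    default_edge_weight_threshold: float = 0.2
    kmeans_k: int = 3
    gs_min: float = 0.95
    mm_min: float = 0.98
    # misc
    seed: int = 0
    verbosity: str = "INFO"

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) else json.loads(text)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "powers"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def hub_criteria(self) -> HubCriteria:
        return HubCriteria(
            edge_weight_threshold=dict(self.edge_weight_threshold),
            default_edge_weight_threshold=self.default_edge_weight_threshold,
            kmeans_k=self.kmeans_k,
            gs_min=self.gs_min,
            mm_min=self.mm_min,
            module_trait_min=self.module_trait_min,
            seed=self.seed,
        )


def _write_provenance(config: PipelineConfig, out: Path, stage: str) -> None:
    record = {
        "tool": "dormabreak",
        "version": __version__,
        "stage": stage,
        "seed": config.seed,
        "config": asdict(config),
    }
    (out / f"provenance_{stage}.json").write_text(json.dumps(record, indent=2, default=str))


def run_chill_pipeline(config: PipelineConfig) -> dict:
    """Sprouting CSV -> CU model + CAS stage models (+ verification)."""
    if not config.sprouting_csv:
        raise ConfigError("chilling pipeline requires sprouting_csv")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        experiment = read_sprouting_csv(config.sprouting_csv)
    except DormabreakError as err:
        raise type(err)(f"[read sprouting] {err}") from err

    log.info("chill-unit table (reference %.1f degC)", config.reference_temperature)
    table = chill_unit_table(experiment, config.reference_temperature)
    table.to_frame().to_csv(out / "chill_unit_table.csv", index=False)

    cu_model = fit_cu_model(table)
    log.info("fitted CU model: %s", cu_model.summary().replace("\n", " | "))
    write_model_json(cu_model, out / "cu_model.json")

    cas_dir = out / "cas"
    cas_dir.mkdir(exist_ok=True)
    cas_models = {}
    for stage in config.stages:
        points = stage_observations(experiment, cu_model, stage)
        model = fit_cas(points, stage, form=config.cas_form)
        points.to_csv(cas_dir / f"stage{stage}_points.csv", index=False)
        write_model_json(model, cas_dir / f"stage{stage}.json")
        cas_models[stage] = model
        log.info("stage %d: %s", stage, model.summary().replace("\n", " | "))

    artifacts = {
        "cu_model": cu_model,
        "cas_models": cas_models,
        "chill_unit_table": table,
    }

    if config.verification_csv:
        held_out = read_sprouting_csv(config.verification_csv)
        pred, obs, rows = [], [], []
        for stage, model in cas_models.items():
            pts = stage_observations(held_out, cu_model, stage)
            p = model.predict(pts["ca"].to_numpy())
            pred.extend(p)
            obs.extend(pts["sprouting_pct"])
            for (_, r), pi in zip(pts.iterrows(), np.atleast_1d(p)):
                rows.append((stage, r.temperature, r.chilling_days, r.ca, pi, r.sprouting_pct))
        stats = verify_predictions(pred, obs)
        pd.DataFrame(
            rows,
            columns=["stage_day", "temperature", "chilling_days", "ca", "predicted", "observed"],
        ).to_csv(out / "verification_points.csv", index=False)
        (out / "verification_report.json").write_text(
            json.dumps(
                {
                    "r_squared": stats.r_squared,
                    "slope": stats.slope,
                    "intercept": stats.intercept,
                    "bias": stats.bias,
                    "n": stats.n,
                },
                indent=2,
            )
        )
        log.info("%s", stats.summary())
        artifacts["verification"] = stats

    _write_provenance(config, out, "chill")
    return artifacts


def run_network_pipeline(config: PipelineConfig) -> dict:
    """Expression + trait CSVs -> modules, statistics and hub screen."""
    if not (config.expression_csv and config.trait_csv):
        raise ConfigError("network pipeline requires expression_csv and trait_csv")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        expr = read_expression_csv(config.expression_csv, config.trait_csv)
    except DormabreakError as err:
        raise type(err)(f"[read expression] {err}") from err

    net = WeightedCoexpressionNetwork(expr, transform=config.transform)
    if config.beta is None:
        soft = net.pick_soft_threshold(powers=config.powers)
        beta = soft.beta
        soft.table.to_csv(out / "soft_threshold.csv", index=False)
        log.info("picked soft threshold beta=%d", beta)
    else:
        beta = config.beta
        log.info("beta override: %d", beta)

    results = net.fit(
        beta=beta,
        min_module_size=config.min_module_size,
        merge_height=config.merge_height,
        min_abs_cor=config.module_trait_min,
    )
    asn = results.assignment
    asn.labels.rename("module").to_csv(out / "modules.csv", index_label="gene_id")
    asn.eigengenes.to_csv(out / "eigengenes.csv", index_label="module")
    pd.DataFrame({"cor": asn.module_trait_cor, "p": asn.module_trait_p}).to_csv(
        out / "module_trait.csv", index_label="module"
    )
    asn.gene_stats.to_csv(out / "gene_stats.csv")

    criteria = config.hub_criteria()
    report = real_hub_genes(asn, criteria, results.tom)
    report.table.to_csv(out / "hubs.csv")
    for module in sorted(set(report.table["module"])):
        edges = module_edge_list(
            results.tom, asn.labels, module, criteria.threshold_for(module)
        )
        export_edges_tsv(edges, out / f"edges_{module}.tsv")

    n_modules = asn.labels[asn.labels != UNASSIGNED].nunique()
    log.info(
        "%d modules, %d significant, %d real hubs",
        n_modules,
        len(results.significant_modules()),
        int(report.table.is_hub.sum()),
    )
    _write_provenance(config, out, "network")
    return {"results": results, "hub_report": report, "beta": beta}
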