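"""Synthetic sprouting experiments and expression matrices with ground truth.

The sprouting generator draws each bud's emergence day from a bounded
uniform window whose centre (delay) decreases, and whose success
probability (plateau) increases, with the chilling accumulation delivered
by the treatment; beyond a supra-optimal accumulation the plateau
declines linearly, reproducing the "excess chilling hurts" effect seen in
real time courses.  The expression generator plants block-correlated
gene modules whose latent profile has an exact, user-chosen Pearson
correlation with the trait vector, on the log scale, then exponentiates
to non-negative FPKM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .chill import ChillUnitModel
from .datatypes import ExpressionMatrix, SproutingExperiment, SproutingRecord
from .errors import ConfigError

# Coefficients of the quadratic chill-unit curve used as the default
# ground truth for simulations (concave, optimum near 3 degC).
DEFAULT_TRUE_CU = (-0.0154, 0.0916, 0.9926)

# Study-scale design: 9 chilling temperatures spanning the effective
# 0-10 degC range and 12 durations (days), with 3 replicate trays of 20
# buds each and 70 warm days of daily observation.
DEFAULT_TEMPERATURES = (0.0, 1.25, 2.5, 3.75, 5.0, 6.25, 7.5, 8.75, 10.0)
DEFAULT_DURATIONS = (5, 11, 15, 18, 22, 27, 32, 36, 52, 61, 71, 81)


@dataclass(frozen=True)
class SproutingSimConfig:
    """Ground truth and design for a simulated chilling experiment.

    plateau(Ca) = min(plateau_max, plateau_rate * Ca) for
    Ca <= supra_optimal_ca, then declining linearly at
    ``supra_decline`` % per Ca (a saturating rise followed by the
    supra-optimal decline); delay(Ca) = delay_min +
    delay_span * exp(-Ca / delay_scale).  The linear-in-Ca rise keeps the
    rising-phase slope of the sprouting curve proportional to the
    accumulated chill below saturation, so per-temperature chill units
    are identifiable from slope ratios.  Each bud sprouts with
    probability plateau(Ca)/100 on day ceil(delay + U) where U is uniform
    on [-sprout_spread, +sprout_spread] days: the replicate-mean curve is
    then a linear ramp of width 2*sprout_spread whose rising-phase slope
    is proportional to the plateau regardless of how many buds sprout
    (an unbounded emergence-day distribution would make the observed
    rising window grow with the sprout count and distort slope ratios).
    Buds past the last observation day are recorded as non-sprouted.
    """

    true_cu: tuple[float, float, float] = DEFAULT_TRUE_CU
    temperatures: tuple[float, ...] = DEFAULT_TEMPERATURES
    durations: tuple[float, ...] = DEFAULT_DURATIONS
    n_buds: int = 20
    replicates: int = 3
    n_days: int = 70
    plateau_max: float = 100.0
    plateau_rate: float = 0.08  # percent of buds per unit Ca below saturation
    supra_optimal_ca: float = 1900.0
    supra_decline: float = 0.01  # percent lost per Ca beyond the supra optimum
    delay_min: float = 14.0
    delay_span: float = 50.0
    delay_scale: float = 500.0
    sprout_spread: float = 6.0  # half-width of the emergence-day window, days
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.plateau_max <= 100:
            raise ConfigError("plateau_max must lie in [0, 100]")
        if self.delay_min < 0 or self.delay_span < 0:
            raise ConfigError("delays must be non-negative")
        if self.sprout_spread < 0:
            raise ConfigError("sprout_spread must be >= 0")
        if self.plateau_rate <= 0 or self.delay_scale <= 0:
            raise ConfigError("plateau_rate and delay_scale must be > 0")
        if self.n_buds <= 0 or self.replicates <= 0 or self.n_days <= 0:
            raise ConfigError("n_buds, replicates and n_days must be positive")

    # -- ground-truth response functions -----------------------------------
    def cu_model(self) -> ChillUnitModel:
        a, b, c = self.true_cu
        return ChillUnitModel(a=a, b=b, c=c)

    def plateau(self, ca: float) -> float:
        """Expected final sprouting percentage at accumulation `ca`."""
        p = min(self.plateau_max, self.plateau_rate * ca)
        if ca > self.supra_optimal_ca:
            p_at_supra = min(self.plateau_max, self.plateau_rate * self.supra_optimal_ca)
            p = p_at_supra - self.supra_decline * (ca - self.supra_optimal_ca)
        return float(np.clip(p, 0.0, 100.0))

    def delay(self, ca: float) -> float:
        """Median emergence day (warming days) at accumulation `ca`."""
        return self.delay_min + self.delay_span * math.exp(-ca / self.delay_scale)


def simulate_sprouting(config: SproutingSimConfig) -> SproutingExperiment:
    """Draw a replicated sprouting experiment from the configured truth."""
    rng = np.random.default_rng(config.seed)
    model = config.cu_model()
    records = []
    for temperature in config.temperatures:
        cu = model.cu_value(temperature) if temperature >= 0 else 0.0
        for duration in config.durations:
            ca = cu * 24.0 * duration
            p_sprout = config.plateau(ca) / 100.0
            loc = config.delay(ca)
            for rep in range(1, config.replicates + 1):
                sprouts = rng.random(config.n_buds) < p_sprout
                days = loc + config.sprout_spread * rng.uniform(-1.0, 1.0, size=config.n_buds)
                day_idx = np.ceil(days).astype(int)
                counts = np.zeros(config.n_days, dtype=int)
                for ok, d in zip(sprouts, day_idx):
                    if ok and d <= config.n_days:
                        counts[max(d, 1) - 1] += 1
                records.append(
                    SproutingRecord(
                        temperature=temperature,
                        chilling_days=duration,
                        replicate=rep,
                        n_buds=config.n_buds,
                        sprouted_by_day=np.cumsum(counts),
                    )
                )
    return SproutingExperiment(records)


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------

# Sprouting percentages of three dormancy states x three replicates:
# endodormant buds barely sprout, ecodormant buds sprout partially once
# conditions allow, nondormant buds sprout nearly fully.
DEFAULT_TRAIT = (2.0, 4.0, 6.0, 55.0, 60.0, 65.0, 90.0, 93.0, 96.0)


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Planted-module expression design.

    Each module m gets a latent per-sample profile with exact Pearson
    correlation ``module_r[m]`` to the trait (0 => trait-independent).
    Member genes are ``loading * latent + N(0, noise_sd)`` on the log
    scale plus a gene-specific baseline, exponentiated to FPKM.  The
    first ``n_hubs_per_module`` genes of each module are engineered hubs:
    maximal loading and no gene-level noise.  Genes beyond
    ``sum(module_sizes)`` are independent background noise.
    """

    n_genes: int = 1000
    module_sizes: tuple[int, ...] = (150, 120, 100, 80, 60, 50)
    module_r: tuple[float, ...] = (0.95, -0.95, 0.0, 0.0, 0.0, 0.0)
    n_samples: int = 9
    trait: tuple[float, ...] = DEFAULT_TRAIT
    loading_range: tuple[float, float] = (0.8, 1.2)
    noise_sd: float = 0.25
    base_log_mean: float = 2.5
    base_log_sd: float = 1.0
    n_hubs_per_module: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.module_sizes) != len(self.module_r):
            raise ConfigError("module_sizes and module_r differ in length")
        if sum(self.module_sizes) > self.n_genes:
            raise ConfigError(
                f"module sizes sum to {sum(self.module_sizes)} > n_genes={self.n_genes}"
            )
        if any(abs(r) > 1 for r in self.module_r):
            raise ConfigError("module-trait correlations must lie in [-1, 1]")
        if len(self.trait) != self.n_samples:
            raise ConfigError("trait length must equal n_samples")
        if any(s < 1 for s in self.module_sizes):
            raise ConfigError("module sizes must be >= 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


@dataclass(frozen=True)
class ExpressionSimResult:
    """Simulated matrix plus the planted ground truth."""

    expr: ExpressionMatrix
    labels: pd.Series  # gene -> planted module name ("background" for noise)
    hubs: pd.Series  # gene -> planted module, engineered hubs only
    latents: pd.DataFrame  # module x sample latent profiles


def _standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


def _module_latents(
    trait: np.ndarray, rs: Sequence[float], rng: np.random.Generator
) -> np.ndarray:
    """Latent profiles with exact trait correlations and orthogonal residuals.

    Each latent is r*z_trait + sqrt(1-r^2)*e_m where the e_m are
    unit-variance, mean-zero and mutually orthogonal (and orthogonal to
    the trait).  The sample correlation between latents m and m' is then
    exactly r_m * r_m': with only a handful of samples, independently
    drawn residuals would let planted modules drift into near-collinearity
    by chance, making them unrecoverable by construction rather than by
    algorithmic failure.
    """
    n = trait.size
    z_t = _standardize(trait)
    basis = [np.ones(n) / math.sqrt(n), z_t / np.linalg.norm(z_t)]
    residuals = []
    for _ in rs:
        e = rng.normal(size=n)
        # orthogonalize against previous residuals while dimensions remain;
        # always against the constant and the trait directions
        against = basis if len(basis) < n else basis[:2]
        for b in against:
            e = e - (e @ b) * b
        e = e / np.linalg.norm(e)
        if len(basis) < n:
            basis.append(e)
        residuals.append(e * math.sqrt(n))  # unit sample variance
    latents = []
    for r, e in zip(rs, residuals):
        latents.append(r * z_t + math.sqrt(max(0.0, 1.0 - r * r)) * e)
    return np.asarray(latents)


def simulate_expression(config: ExpressionSimConfig) -> ExpressionSimResult:
    """Draw an FPKM matrix with planted trait-correlated modules."""
    rng = np.random.default_rng(config.seed)
    n_genes, n_samples = config.n_genes, config.n_samples
    trait = np.asarray(config.trait, dtype=float)
    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    sample_ids = [f"S{j + 1}" for j in range(n_samples)]

    log_expr = np.empty((n_genes, n_samples))
    labels = np.array(["background"] * n_genes, dtype=object)
    hub_mask = np.zeros(n_genes, dtype=bool)
    latents = {}

    lo, hi = config.loading_range
    module_latents = _module_latents(trait, config.module_r, rng)
    g = 0
    for m, (size, r) in enumerate(zip(config.module_sizes, config.module_r), start=1):
        name = f"M{m}"
        latent = module_latents[m - 1]
        latents[name] = latent
        for j in range(size):
            is_hub = j < config.n_hubs_per_module
            loading = hi if is_hub else rng.uniform(lo, hi)
            noise = 0.0 if is_hub else rng.normal(0.0, config.noise_sd, size=n_samples)
            # engineered hubs are strongly expressed: a low baseline would
            # push samples toward zero FPKM where the log transform is
            # nonlinear and would wash out the planted correlations
            base = (
                config.base_log_mean + config.base_log_sd
                if is_hub
                else rng.normal(config.base_log_mean, config.base_log_sd)
            )
            log_expr[g] = base + loading * latent + noise
            labels[g] = name
            hub_mask[g] = is_hub
            g += 1
    # background genes: independent noise around their own baselines
    for i in range(g, n_genes):
        base = rng.normal(config.base_log_mean, config.base_log_sd)
        log_expr[i] = base + rng.normal(0.0, 1.0, size=n_samples)

    values = np.exp(log_expr)
    expr = ExpressionMatrix(gene_ids, sample_ids, values, trait)
    labels_s = pd.Series(labels, index=gene_ids, name="module")
    hubs_s = labels_s[hub_mask]
    latents_df = pd.DataFrame(latents, index=sample_ids).T
    return ExpressionSimResult(expr=expr, labels=labels_s, hubs=hubs_s, latents=latents_df)
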