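import numpy as np
import pytest
from hypothesis import settings

# property tests run a fixed example sequence so suite outcomes are
# reproducible across runs
settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from dormabreak import (
    ChillUnitModel,
    SproutingExperiment,
    SproutingRecord,
)

# Coefficients of the reference quadratic chill-unit curve used
# throughout the suite (concave, optimum near 3 degC).
REFERENCE_COEFFS = (-0.0154, 0.0916, 0.9926)


@pytest.fixture
def reference_model() -> ChillUnitModel:
    return ChillUnitModel(*REFERENCE_COEFFS)


def make_record(counts, temperature=0.0, chilling_days=15.0, replicate=1, n_buds=20):
    return SproutingRecord(
        temperature=temperature,
        chilling_days=chilling_days,
        replicate=replicate,
        n_buds=n_buds,
        sprouted_by_day=np.asarray(counts, dtype=int),
    )


def make_experiment(*records) -> SproutingExperiment:
    return SproutingExperiment(records)


@pytest.fixture
def tiny_experiment() -> SproutingExperiment:
    """Two treatments x two replicates over five warming days."""
    return make_experiment(
        make_record([0, 0, 5, 10, 15], temperature=0.0, chilling_days=15, replicate=1),
        make_record([0, 0, 5, 11, 17], temperature=0.0, chilling_days=15, replicate=2),
        make_record([0, 2, 6, 12, 16], temperature=4.0, chilling_days=15, replicate=1),
        make_record([0, 2, 8, 12, 18], temperature=4.0, chilling_days=15, replicate=2),
    )
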