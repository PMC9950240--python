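"""Shared fixtures: a fast sampler configuration and small simulated datasets."""

import pytest

from avmemory import (
    ModelConfig,
    RecognitionCounts,
    design_for,
    simulate_experiment,
    to_sdt_cells,
)


@pytest.fixture(scope="session")
def fast_config() -> ModelConfig:
    """Sampler settings sized for unit tests, not for publication-grade runs."""
    return ModelConfig(n_chains=2, n_adapt=300, n_burnin=200, n_iter=1500)


@pytest.fixture(scope="session")
def small_counts() -> RecognitionCounts:
    return RecognitionCounts(n_a=200, y_a=110, n_v=200, y_v=124, n_av=200, y_av=150)


@pytest.fixture(scope="session")
def exp1a_trials():
    spec = design_for("1a", n_participants=8)
    return simulate_experiment(spec, seed=7)


@pytest.fixture(scope="session")
def exp1a_cells(exp1a_trials):
    return to_sdt_cells(exp1a_trials)
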