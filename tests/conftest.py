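import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from degstrat import (
    SimulationConfig,
    simulate_annotation,
    simulate_expression,
)


@pytest.fixture(scope="session")
def default_sim():
    """Default study conditions: 5000 genes, 4 reps/cell, effect 2.0, noise 0.5."""
    cfg = SimulationConfig(seed=11)
    em, truth = simulate_expression(cfg)
    return cfg, em, truth


@pytest.fixture(scope="session")
def default_ann(default_sim):
    _, _, truth = default_sim
    return simulate_annotation(truth, term_purity=1.0, seed=12)


@pytest.fixture(scope="session")
def noiseless_sim():
    cfg = SimulationConfig(noise_sd=0.01, seed=13)
    return cfg, *simulate_expression(cfg)


@pytest.fixture(scope="session")
def small_sim():
    """Small matrix for fast unit-level checks."""
    counts = {
        "common_time_up": 30,
        "common_time_down": 30,
        "treated_only_time": 10,
        "control_only_time": 10,
        "early_up": 20,
        "early_down": 20,
        "constant_up": 20,
        "constant_down": 20,
        "delayed_up": 20,
        "delayed_down": 20,
    }
    cfg = SimulationConfig(n_genes=600, planted_counts=counts, seed=7)
    return cfg, *simulate_expression(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
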