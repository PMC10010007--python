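import numpy as np
import pandas as pd
import pytest

from tmzpgx.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-patient synthetic study shared by read-only tests."""
    cfg = SimulationConfig(n_patients=40, n_genes=300, seed=1)
    bundle, truth = simulate_cohort(cfg)
    return cfg, bundle, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
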