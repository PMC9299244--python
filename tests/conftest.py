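import numpy as np
import pandas as pd
import pytest

from vaxsurv import SimulationConfig, simulate_tables
from vaxsurv.synthetic_data import confounded_scenario


@pytest.fixture(scope="session")
def confounded_config():
    """A desk-scale slice of the standard confounded scenario.

    Visit propensity depends on frailty more strongly than vaccination
    uptake does, so a visit-day comparator over-samples frail people while
    a random-day comparator under-samples them relative to the vaccinated.
    """
    return confounded_scenario(n_persons=8000, n_negative_controls=10, seed=11)


@pytest.fixture(scope="session")
def confounded_tables(confounded_config):
    tables, defs = simulate_tables(confounded_config)
    return tables, defs, confounded_config


@pytest.fixture(scope="session")
def null_config():
    """No confounding, no seasonality: every design should be unbiased."""
    return SimulationConfig(
        n_persons=5000,
        n_negative_controls=6,
        baseline_rate=0.06,
        seed=7,
    )


@pytest.fixture(scope="session")
def null_tables(null_config):
    tables, defs = simulate_tables(null_config)
    return tables, defs, null_config
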