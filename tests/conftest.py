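import numpy as np
import pandas as pd
import pytest

from rxaccess import ScenarioConfig, generate_scenario
from rxaccess.network import RoadNetwork


@pytest.fixture
def triangle_network() -> RoadNetwork:
    """A–B 1.0, B–C 1.0 and a long direct A–C 3.0 edge."""
    nodes = pd.DataFrame(
        {"node_id": ["A", "B", "C"], "x_km": [0.0, 1.0, 2.0], "y_km": [0.0, 0.0, 0.0]}
    )
    edges = pd.DataFrame(
        {
            "node_a": ["A", "B", "A"],
            "node_b": ["B", "C", "C"],
            "length_km": [1.0, 1.0, 3.0],
        }
    )
    return RoadNetwork.from_tables(nodes, edges)


@pytest.fixture(scope="session")
def small_config() -> ScenarioConfig:
    """A 4×4-tract region sized for fast CLI / round-trip tests."""
    return ScenarioConfig(
        seed=3,
        tract_rows=4,
        tract_cols=4,
        n_facilities=12,
        n_border_facilities=2,
        n_foreign_facilities=2,
        n_water_tracts=1,
        n_low_pop_tracts=1,
    )


@pytest.fixture(scope="session")
def small_scenario(small_config):
    return generate_scenario(small_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
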