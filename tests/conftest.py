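import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # local oracles module

from savannagrad.aggregate import aggregate_grid
from savannagrad.pipeline import metrics_table
from savannagrad.synthetic import ScenarioConfig, simulate_landscape


@pytest.fixture(scope="session")
def small_config():
    """A 12x12-block scenario: fast, but large enough for model fits."""
    return ScenarioConfig(nx=12, ny=12, boundary_col=6, seed=42)


@pytest.fixture(scope="session")
def small_grid(small_config):
    return simulate_landscape(small_config)


@pytest.fixture(scope="session")
def small_blocks(small_grid):
    return aggregate_grid(small_grid)


@pytest.fixture(scope="session")
def small_metrics(small_blocks, small_grid):
    return metrics_table(small_blocks, small_grid.colmap)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
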