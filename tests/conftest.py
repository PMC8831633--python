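import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import climstab as cs

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def grid():
    return cs.Grid.regular(10, 12, origin=(0.0, 10.0), resolution=0.1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def make_layer(grid):
    """Layer factory on the shared grid; scalars are broadcast."""
    def _make(values, variable_id="bio1", period_id="T1", g=None):
        g = g or grid
        arr = np.broadcast_to(np.asarray(values, dtype=np.float32),
                              g.shape).copy()
        return cs.RasterLayer(g, arr, variable_id=variable_id,
                              period_id=period_id)
    return _make


@pytest.fixture
def make_stack(make_layer):
    """Stack from per-period scalar or array values."""
    def _make(per_period, variable_id="bio1"):
        layers = [make_layer(v, variable_id=variable_id,
                             period_id=f"T{i + 1}")
                  for i, v in enumerate(per_period)]
        return cs.RasterStack.from_layers(layers)
    return _make


@pytest.fixture(scope="session")
def past_world():
    """Small deterministic past world shared across tests (read-only)."""
    return cs.make_world(cs.WorldSpec(map_set="past", n_rows=40,
                                      n_cols=60, master_seed=7))


@pytest.fixture(scope="session")
def future_world():
    return cs.make_world(cs.WorldSpec(map_set="future", n_rows=40,
                                      n_cols=60, master_seed=7))


@pytest.fixture
def random_stack(grid, rng):
    """12-period random stack with scattered NoData for oracle tests."""
    layers = []
    for t in range(12):
        vals = rng.normal(10.0, 3.0, grid.shape).astype(np.float32)
        nan_mask = rng.random(grid.shape) < 0.1
        vals[nan_mask] = np.nan
        layers.append(cs.RasterLayer(grid, vals, variable_id="bio1",
                                     period_id=f"T{t + 1}"))
    return cs.RasterStack.from_layers(layers)
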