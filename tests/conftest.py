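import numpy as np
import pytest

from colliculus import (
    SyntheticConfig,
    generate_dataset,
    make_map_population,
)


@pytest.fixture(scope="session")
def small_population():
    """A small but map-spanning synthetic population (fast to simulate)."""
    cfg = SyntheticConfig(n_cells=64, seed=3)
    return cfg, make_map_population(cfg)


@pytest.fixture(scope="session")
def small_dataset():
    """Single-unit sessions from a mid-map band of cells, with their config.

    The band must be dense enough for the decoder to produce sensible
    saccades (the spike-vector sum approximates an integral over the
    population), but small enough to generate quickly.
    """
    cfg = SyntheticConfig(n_cells=24, u_range=(1.2, 3.0), v_range=(-0.8, 0.8), seed=5)
    ds = generate_dataset(cfg, n_reps=1, seed=5)
    return cfg, ds


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
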