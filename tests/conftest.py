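import numpy as np
import pytest

from nnmap.populations import (
    assign_surface_values,
    generate_unit_pattern,
    make_predictions,
    truncate_units,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


@pytest.fixture(scope="session")
def threep_population():
    """A random-pattern unit population with 3P frame data (surface 1)."""
    pop = generate_unit_pattern("random", (500, 1000, 1500), make_rng(777))[-1]
    pop = assign_surface_values(pop, 1)
    pop = truncate_units(pop, 4.0)
    return make_predictions(pop)
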