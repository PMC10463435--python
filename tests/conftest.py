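import numpy as np
import pandas as pd
import pytest

from stratq import SyntheticConfig, generate_city_lattice, generate_pollutants


@pytest.fixture
def rng():
    return np.random.default_rng(20150901)


@pytest.fixture
def small_config():
    return SyntheticConfig(n_cities=30, n_individuals=900, seed=11)


@pytest.fixture
def small_cities(small_config):
    return generate_pollutants(generate_city_lattice(small_config), small_config)


@pytest.fixture
def chain_weights():
    """Binary chain adjacency 1-2-3-4 as a SpatialWeights object."""
    from stratq import SpatialWeights

    m = np.array([[0, 1, 0, 0],
                  [1, 0, 1, 0],
                  [0, 1, 0, 1],
                  [0, 0, 1, 0]], dtype=float)
    return SpatialWeights(["a", "b", "c", "d"], m)


@pytest.fixture
def individuals_frame():
    """Hand-built individual records: one city, four middle-aged adults
    with BMIs {22, 25, 29, 23} via height 200 cm (so BMI = weight / 4)."""
    return pd.DataFrame({
        "id": ["r1", "r2", "r3", "r4"],
        "city_id": ["X"] * 4,
        "age": [50, 51, 52, 53],
        "sex": ["male", "female", "male", "female"],
        "height_cm": [200.0] * 4,
        "weight_kg": [88.0, 100.0, 116.0, 92.0],
    })
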