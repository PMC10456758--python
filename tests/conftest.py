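import numpy as np
import pytest
from hypothesis import settings

import ndentropy as nd

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def gas_fixture() -> nd.PointSet:
    """Fixed-seed uniform gas: dispersed-state stand-in (N=500, 1000x1000 box)."""
    return nd.uniform_gas(500, (1000.0, 1000.0), seed=7)


@pytest.fixture(scope="session")
def clusters_fixture() -> nd.PointSet:
    """Fixed-seed Gaussian clusters: aggregated-state stand-in (5 x 100, sigma=10)."""
    return nd.gaussian_clusters(5, 100, 10.0, (1000.0, 1000.0), seed=7)


@pytest.fixture(scope="session")
def hex_lattice() -> nd.PointSet:
    """12x12 periodic triangular lattice with spacing 10: H_NDist = 0 reference."""
    return nd.hexagonal_lattice(12, 12, 10.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
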