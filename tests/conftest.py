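"""Shared fixtures: calibrated defaults and fast (coarse) spatial settings."""

import numpy as np
import pytest

from actocap.params import Concentrations, Geometry, RateParams
from actocap.spatial import RadialGrid, SpatialParams


@pytest.fixture(scope="session")
def rates():
    return RateParams()


@pytest.fixture(scope="session")
def geometry():
    return Geometry()


@pytest.fixture(scope="session")
def paper_mix():
    """3 µM actin, 0.3 µM VCA, 0.3 µM Arp2/3, 13.5 µM profilin."""
    return Concentrations()


@pytest.fixture(scope="session")
def coarse_grid():
    """Coarse radial grid for fast spatial tests."""
    return RadialGrid(n_cells=48)


@pytest.fixture(scope="session")
def fine_grid():
    return RadialGrid(n_cells=128)


@pytest.fixture(scope="session")
def spatial_defaults():
    return SpatialParams()


@pytest.fixture(scope="session")
def t_grid_5min():
    return np.linspace(0.0, 300.0, 601)
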