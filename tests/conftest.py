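import numpy as np
import pytest

from stationopt import RegionSpec, build_road_network, generate_region
from stationopt.geodata import patients_to_arrays


@pytest.fixture(scope="session")
def default_region():
    """Full-size synthetic region at generator defaults (the study conditions)."""
    return generate_region(RegionSpec(seed=11))


@pytest.fixture(scope="session")
def default_arrays(default_region):
    return patients_to_arrays(default_region.patients)


@pytest.fixture(scope="session")
def small_region():
    """A small region for fast end-to-end and I/O tests."""
    spec = RegionSpec(
        extent=(40_000.0, 40_000.0),
        n_hubs=6,
        n_patients=800,
        n_stations=8,
        grid_pitch=5_000.0,
        seed=42,
    )
    return generate_region(spec)


@pytest.fixture()
def square_net():
    """4-node square with one long southern detour.

    0 -(1000)- 1
    |          |
    (1000)   (1000)
    |          |
    3 -(3000)- 2   (3 -> 2 direct is 3000 m at 30 km/h; all others 60 km/h)
    """
    nodes = np.array([[0, 1000], [1000, 1000], [1000, 0], [0, 0]], dtype=float)
    edges = [
        (0, 1, 1000.0, 60.0),
        (1, 2, 1000.0, 60.0),
        (3, 2, 3000.0, 30.0),
        (0, 3, 1000.0, 60.0),
    ]
    return build_road_network(nodes, edges)


@pytest.fixture()
def l_net():
    """Two unit-km legs at a right angle (the Manhattan-diagonal example)."""
    nodes = np.array([[0, 0], [1000, 0], [1000, 1000]], dtype=float)
    edges = [(0, 1, 1000.0, 50.0), (1, 2, 1000.0, 50.0)]
    return build_road_network(nodes, edges)
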