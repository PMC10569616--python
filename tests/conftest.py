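import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import perfusim as pf
from perfusim.geometry import ARTERY, VEIN

settings.register_profile(
    "default", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def bc():
    return pf.BoundaryConditions(10600.0, 1600.0)


@pytest.fixture
def chain_mesh():
    """4x1 chain: artery inlet on the left, vein outlet on the right."""
    label = np.zeros((4, 1), dtype=np.int8)
    label[0, 0] = ARTERY
    label[3, 0] = VEIN
    return pf.build_mesh(4, 1, 1e-3, None, label, [(0, 0)], [(3, 0)])


@pytest.fixture
def grid_mesh():
    """5x5 all-active grid, inlet artery at (0,0), outlet vein at (4,4)."""
    label = np.zeros((5, 5), dtype=np.int8)
    label[0, 0] = ARTERY
    label[4, 4] = VEIN
    return pf.build_mesh(5, 5, 1e-3, None, label, [(0, 0)], [(4, 4)])


@pytest.fixture
def uniform_params():
    def make(mesh, **kw):
        return pf.ParameterFields.uniform(mesh, **kw)

    return make


@pytest.fixture(scope="session")
def twin_dataset():
    """Desk-scale synthetic truth shared by the slower integration tests."""
    return pf.run_truth_experiment(pf.twin_config(), seed=1)
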