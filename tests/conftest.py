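import numpy as np
import pytest

from ttfield import device_model as dm


@pytest.fixture
def default_geometry():
    return dm.DeviceGeometry()


@pytest.fixture
def default_materials():
    return dm.MaterialSet()


@pytest.fixture
def default_network(default_geometry, default_materials):
    return dm.build_network(default_geometry, default_materials)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_network(rng: np.random.Generator) -> dm.CircuitNetwork:
    """A random series chain: 3-9 elements, mixed resistors and RC pairs,
    one element tagged as the gel."""
    n = int(rng.integers(3, 10))
    gel_index = int(rng.integers(0, n))
    elements = []
    for i in range(n):
        R = float(10 ** rng.uniform(0, 9))
        if i != gel_index and rng.random() < 0.5:
            C = float(10 ** rng.uniform(-14, -9))
            elements.append(dm.CircuitElement(f"rc{i}", "rc_parallel", R, C))
        else:
            elements.append(
                dm.CircuitElement(f"r{i}", "resistor", R, is_gel=(i == gel_index))
            )
    return dm.CircuitNetwork(tuple(elements))
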