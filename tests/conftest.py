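import numpy as np
import pytest

from pollenpat import (
    GMParameters,
    steady_state,
    ring_from_front_area,
    sphere_from_front_area,
)


@pytest.fixture(scope="session")
def params():
    return GMParameters()


@pytest.fixture(scope="session")
def ss(params):
    return steady_state(params)


@pytest.fixture(scope="session")
def ring550():
    return ring_from_front_area(550.0)


@pytest.fixture(scope="session")
def sphere550():
    return sphere_from_front_area(550.0, resolution=3)


@pytest.fixture(scope="session")
def sphere550_fine():
    return sphere_from_front_area(550.0, resolution=4)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
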