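import numpy as np
import pytest

from dynmodnet.atlas import SystemMap


@pytest.fixture(scope="session")
def default_map() -> SystemMap:
    return SystemMap.default()


@pytest.fixture(scope="session")
def mini_map() -> SystemMap:
    """Twelve nodes, three per named system (desk-scale scenario)."""
    return SystemMap(tuple(np.repeat(["SMN", "DMN", "VN", "ATN"], 3)))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
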