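import numpy as np
import pytest

from whiskvis.network import NetworkParams, StimulusProtocol
from whiskvis.synth import (
    BarrelGenConfig, gen_barrel_map, gen_visual_space, gen_whisker_array,
)


@pytest.fixture(scope="session")
def default_params() -> NetworkParams:
    return NetworkParams()


@pytest.fixture(scope="session")
def default_protocol() -> StimulusProtocol:
    return StimulusProtocol()


@pytest.fixture(scope="session")
def whisker_array():
    array, truth = gen_whisker_array(seed=1)
    return array, truth


@pytest.fixture(scope="session")
def visual_space():
    vmap, _ = gen_visual_space(seed=1)
    return vmap


@pytest.fixture(scope="session")
def barrel_data():
    """Uniform (unenriched) barrel field with cells in two layers."""
    return gen_barrel_map(BarrelGenConfig(), seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
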