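import numpy as np
import pytest

from curtainkit.presets import get_preset
from curtainkit.substrate import build_lambda_map


@pytest.fixture(scope="session")
def lambda_map():
    return build_lambda_map()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def diffusion_preset():
    return get_preset("yPCNA_homoduplex_diffusion")
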