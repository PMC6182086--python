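import numpy as np
import pytest

from rnnplast.networks import (default_architecture, default_init,
                               init_parameters)
from rnnplast.presets import scaled_task_config


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def hf_setup():
    arch = default_architecture("hf", 20)
    params = init_parameters(arch, default_init("hf", arch),
                             np.random.default_rng(7))
    return arch, params, scaled_task_config("hf", seed=7)


@pytest.fixture
def pycog_setup():
    arch = default_architecture("pycog", 20)
    params = init_parameters(arch, default_init("pycog", arch),
                             np.random.default_rng(8))
    return arch, params, scaled_task_config("pycog", seed=8)


@pytest.fixture
def pyrl_setup():
    arch = default_architecture("pyrl_policy", 15, seed=9)
    params = init_parameters(arch, default_init("pyrl", arch),
                             np.random.default_rng(9))
    return arch, params, scaled_task_config("pyrl", seed=9)
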