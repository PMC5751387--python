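import numpy as np
import pytest

from adaptref import load_builtin_montage


@pytest.fixture(scope="session")
def occipital():
    return load_builtin_montage("occipital_1020")


@pytest.fixture(scope="session")
def gait_montage():
    return load_builtin_montage("gait_1020")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
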