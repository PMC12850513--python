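import numpy as np
import pytest

from cealbp import load_default_config


@pytest.fixture(scope="session")
def default_config():
    return load_default_config()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def ppt_rows():
    return np.array(
        [[0.731, 0.268, 0.001], [0.472, 0.334, 0.194], [0.612, 0.321, 0.067]]
    )


@pytest.fixture(scope="session")
def pt_rows():
    return np.array(
        [[0.731, 0.268, 0.001], [0.052, 0.765, 0.183], [0.209, 0.569, 0.222]]
    )


@pytest.fixture(scope="session")
def ppt_alphas():
    return np.array(
        [[20.995, 7.686, 0.022], [2.614, 1.618, 1.034], [22.413, 11.299, 3.048]]
    )
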