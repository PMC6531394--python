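import numpy as np
import pytest

from trimerqsp import load_parameters


@pytest.fixture(scope="session")
def mouse_params():
    """HCT-116 adoptive-transfer mouse context (the best-characterized one)."""
    return load_parameters("hct116_adoptive")


@pytest.fixture(scope="session")
def mouse_params_engrafted():
    return load_parameters("hct116_engrafted")


@pytest.fixture(scope="session")
def sum149_params():
    return load_parameters("sum149_adoptive")


@pytest.fixture(scope="session")
def human_params():
    return load_parameters("human")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
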