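import numpy as np
import pytest

from dopadyn import ModelVariant, default_params


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def full_variant():
    return ModelVariant.full()


@pytest.fixture(scope="session")
def reduced_variant():
    return ModelVariant.reduced()


@pytest.fixture(scope="session")
def v_grid():
    return np.linspace(-120.0, 60.0, 361)
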