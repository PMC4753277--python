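import numpy as np
import pytest

from ampakit import core_model as cm


@pytest.fixture
def lif_params():
    return cm.default_lif_params()


@pytest.fixture
def fast_kernel():
    return cm.default_kernel(tau_decay=3.0)


@pytest.fixture
def slow_kernel():
    return cm.default_kernel(tau_decay=5.0)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
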