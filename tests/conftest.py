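import numpy as np
import pytest

from greedychemo import ModelParams


@pytest.fixture
def rng():
    return np.random.default_rng(20240731)


@pytest.fixture
def params_eps5():
    """epsilon = 5, homing radius 5."""
    return ModelParams(a=1.0, v=0.1, alpha=0.5, D=1.0)


@pytest.fixture
def params_eps10():
    """Critical-ensemble configuration: epsilon = 10, homing radius 10."""
    return ModelParams(a=1.0, v=0.1, alpha=1.0, D=1.0)
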