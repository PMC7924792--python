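import math

import pytest

from evorescue import ModelParams


@pytest.fixture
def coop_params():
    """Default cooperation parameter set (rescue-relevant regime)."""
    return ModelParams(model_variant="cooperation")


@pytest.fixture
def baseline_params():
    return ModelParams(model_variant="baseline", rho=0.0)


@pytest.fixture
def mutualism_params():
    return ModelParams(model_variant="mutualism")


@pytest.fixture
def cheater_params():
    return ModelParams(model_variant="cheater")


@pytest.fixture
def unbounded():
    """Keyword overrides that turn off the logistic term and the Allee
    effect, for comparisons against bare exponential closed forms."""
    return dict(K=math.inf, N_c=0.0, rho=0.0)
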