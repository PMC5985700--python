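import numpy as np
import pytest

from misclassbias import Scenario

#: frozen master seed for Monte-Carlo tests
MASTER_SEED = 20180528


@pytest.fixture
def rng():
    return np.random.default_rng(MASTER_SEED)


@pytest.fixture
def base_scenario():
    """The high-incidence, low-prevalence disease context with the default exposure."""
    return Scenario(prevalence=0.05, incidence=0.1, true_rr=3.0, seed=MASTER_SEED)
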