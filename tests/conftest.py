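import numpy as np
import pytest

from delaymcmc.network import DelayDistribution, build_two_step_model


@pytest.fixture(scope="session")
def two_step():
    """The benchmark two-step activation network and generative parameters."""
    g = DelayDistribution.gamma(3.6, 0.6)
    net, params = build_two_step_model(10.0, 60.0, 100.0, 0.05, g, g)
    return net, params


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
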