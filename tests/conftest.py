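import numpy as np
import pytest

from frrphys import synthetic
from frrphys.frr_model import FlashletProtocol


@pytest.fixture(scope="session")
def protocol():
    return FlashletProtocol()


@pytest.fixture(scope="session")
def scenarios():
    """Noiseless scenarios for all four species presets."""
    return {name: synthetic.make_scenario(name, seed=1, noise_cv=0.0)
            for name in synthetic.PRESET_NAMES}


@pytest.fixture(scope="session")
def tp_replete(scenarios):
    return scenarios["Tp"].phase("replete")


def assert_close(a, b, rtol=1e-9, atol=0.0):
    np.testing.assert_allclose(a, b, rtol=rtol, atol=atol)
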