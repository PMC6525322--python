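import numpy as np
import pytest

from plastwm import ModelParams, canonical_params


@pytest.fixture(scope="session")
def params() -> ModelParams:
    """The calibrated canonical configuration."""
    return canonical_params()


@pytest.fixture(scope="session")
def quiet_params(params) -> ModelParams:
    """Canonical configuration with the noise switched off."""
    return params.replace(noise_sigma=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
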