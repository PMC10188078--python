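import numpy as np
import pytest
from hypothesis import settings

import layreq as lq
from layreq import trial

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def design():
    return trial.reference_design()


@pytest.fixture(scope="session")
def oxide_ep_model():
    """Linear broken-line truth for the oxide-arm egg-production response."""
    return trial.FITTED_MODELS["egg_production"]["oxide"]


@pytest.fixture(scope="session")
def sulphate_ep_model():
    """Quadratic broken-line truth for the sulphate-arm response."""
    return trial.FITTED_MODELS["egg_production"]["sulphate"]


@pytest.fixture(scope="session")
def oxide_doses(design):
    return design.doses(design.arm("oxide"))


@pytest.fixture(scope="session")
def sulphate_doses(design):
    return design.doses(design.arm("sulphate"))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def noise_free_replicates(design):
    """Replicate table where every trait sits exactly on its truth curve."""
    truths = lq.default_truths(noise=False)
    return lq.simulate_replicates(design, truths, seed=1)
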