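import dataclasses

import numpy as np
import pytest

from pvsdwi import AcquisitionParams, PhantomSpec, simulate
from pvsdwi import phantom as ph


@pytest.fixture(scope="session")
def default_params():
    return AcquisitionParams()


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def noiseless_phantom(default_spec, default_params):
    """Noiseless baseline phantom: (volume, ground truth). Session-cached."""
    return simulate(default_spec, default_params)


@pytest.fixture(scope="session")
def noisy_phantom(default_spec, default_params):
    """Baseline phantom at CSF-b0 SNR 50, seed 0."""
    sigma = ph.sigma_for_snr(default_spec, default_params, 50.0)
    spec = dataclasses.replace(default_spec, noise_sigma=sigma, seed=0)
    return simulate(spec, default_params)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
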