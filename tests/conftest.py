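"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pytest

from deepcsd import csd, simulate
from deepcsd.simulate import DWIVolume, _noiseless_volume


@pytest.fixture(scope="session")
def scheme96():
    return simulate.make_gradient_scheme(96, bvalue=2000.0, n_b0=1, seed=7)


@pytest.fixture(scope="session")
def scheme60():
    return simulate.make_gradient_scheme(60, bvalue=2000.0, n_b0=1, seed=3)


@pytest.fixture(scope="session")
def phantom16():
    return simulate.make_phantom((16, 16, 16), seed=1)


@pytest.fixture(scope="session")
def noiseless_volume(phantom16, scheme96):
    data = _noiseless_volume(phantom16, scheme96, s0=1.0)
    return DWIVolume(data, scheme96, phantom16.wm_mask, s0=1.0)


@pytest.fixture(scope="session")
def response96(noiseless_volume, phantom16):
    return csd.estimate_response(noiseless_volume, phantom16.single_fiber_mask)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
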