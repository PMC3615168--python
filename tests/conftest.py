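import numpy as np
import pytest

from gutsurv import AcuteTestDesign, SDParams, simulate_acute_test

CARP_LIKE_SD = SDParams(ke=1.0, kk=1.42, z=4.06, h_controls=0.018)


@pytest.fixture(scope="session")
def carp_like_params():
    return CARP_LIKE_SD


@pytest.fixture(scope="session")
def acute_dataset():
    """One seeded acute-test draw from the default (carp-like SD) design."""
    return simulate_acute_test(AcuteTestDesign(n_fish=60, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
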