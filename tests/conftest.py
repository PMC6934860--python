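import numpy as np
import pytest

from mcsmdr.synthetic import PHENOTYPES, SpheroidGeometry


@pytest.fixture(scope="session")
def geometry128():
    """Mid-frame spheroid that fits a 128x128 frame."""
    return SpheroidGeometry(center=(64.0, 64.0), radius=40.0,
                            boundary_softness=3.0,
                            inhomogeneity_amplitude=0.3,
                            background_noise_sd=60.0)


@pytest.fixture(scope="session")
def sensitive():
    return PHENOTYPES["sensitive"]


@pytest.fixture(scope="session")
def moderate():
    return PHENOTYPES["moderate"]


@pytest.fixture(scope="session")
def resistant():
    return PHENOTYPES["resistant"]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
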