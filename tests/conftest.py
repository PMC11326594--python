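import numpy as np
import pytest

from folliscan.phantom import default_pcos_spec, generate_phantom
from folliscan.preprocess import preprocess_image


@pytest.fixture(scope="session")
def pcos_phantom():
    """One 12-follicle phantom, generated once per session."""
    return generate_phantom(default_pcos_spec(n_follicles=12, seed=7))


@pytest.fixture(scope="session")
def preprocessed_pcos(pcos_phantom):
    return preprocess_image(pcos_phantom.image)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
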