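import numpy as np
import pytest

from lbdgrad.datatypes import AnalysisConfig
from lbdgrad.synthetic import make_parcel_sphere, make_template


@pytest.fixture(scope="session")
def small_config():
    return AnalysisConfig(n_components=5, sparsity=0.9, alpha=0.5, seed=0)


@pytest.fixture(scope="session")
def template60():
    """A 60-region structural template with its latent gradient."""
    return make_template(60, seed=1)


@pytest.fixture(scope="session")
def sphere200():
    return make_parcel_sphere(200, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
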