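import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mpdepth import optics

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    """Model defaults: 900 nm, NA 0.8, n 1.33, g 0.9, l 200 µm, m 2."""
    return optics.OpticalParameters()


@pytest.fixture(scope="session")
def draft():
    return optics.DRAFT_QUADRATURE


@pytest.fixture(scope="session")
def scatter_free(params):
    """Parameters in the no-scattering limit (l -> inf, fixed exclusion)."""
    return params.replace(scattering_length_um=1e12, exclusion_depth_um=40.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
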