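import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tomovessel import Geometry, analytic_project, make_shepp_logan, rasterize

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def shepp_logan():
    return make_shepp_logan()


@pytest.fixture(scope="session")
def truth128(shepp_logan):
    return rasterize(shepp_logan, 128)


@pytest.fixture(scope="session")
def geom128():
    return Geometry.for_grid(128, 180)


@pytest.fixture(scope="session")
def sino128(shepp_logan, geom128):
    """Noiseless analytic Shepp-Logan sinogram at 180 half-turn angles."""
    return analytic_project(shepp_logan, geom128)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
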