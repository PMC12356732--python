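import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from laminarct import RibbonSpec, generate_ribbon

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_ribbon():
    """Noise-free, flat default phantom shared across tests."""
    return generate_ribbon(RibbonSpec())


@pytest.fixture(scope="session")
def curved_ribbon():
    return generate_ribbon(RibbonSpec(curvature=0.3))


@pytest.fixture()
def parallel_boundaries():
    """Two straight horizontal contours 13 px apart, 10 points each."""
    from laminarct import BoundaryPair
    x = np.arange(10, dtype=float)
    sup = np.column_stack([x, np.full(10, 5.0)])
    deep = np.column_stack([x, np.full(10, 18.0)])
    return BoundaryPair(sup, deep, pixel_mm=0.1875)
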