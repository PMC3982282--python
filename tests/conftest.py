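import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gwtedge import paperlike_spec, render_phantom

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def phantom_out():
    """The shipped 256x256 paperlike phantom, rendered once."""
    return render_phantom(paperlike_spec())


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
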