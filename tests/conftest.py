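import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def perfect_curve():
    """Exact doubling chemistry: slope -3.3219, intercept 30, eff 100%."""
    from telopipe.quant import fit_standard_curve

    return fit_standard_curve([(10, 26.678072), (1, 30.0), (0.1, 33.321928)], target="T")
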