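import matplotlib
import pytest
from hypothesis import HealthCheck, settings

matplotlib.use("Agg")

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def default_subject():
    from nirsbf import make_subject

    return make_subject({}, seed=1)


@pytest.fixture
def noiseless_optics():
    from nirsbf import OpticsParams

    return OpticsParams(noise_sd=0.0, pulse_amp=0.0)


@pytest.fixture
def default_optics():
    from nirsbf import OpticsParams

    return OpticsParams()
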