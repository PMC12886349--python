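import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scheme():
    from qeegnorm.bands import make_band_scheme
    return make_band_scheme()


@pytest.fixture(scope="session")
def tdc_features():
    """Reference-like 96 x 35 feature matrix with planted band structure."""
    from qeegnorm.synthetic import tdc_like_cohort_spec, gen_cohort_features
    fm, truth = gen_cohort_features(tdc_like_cohort_spec(seed=42))
    return fm


@pytest.fixture(scope="session")
def table2():
    from qeegnorm.clinical import load_table2
    return load_table2()


@pytest.fixture()
def rng():
    # function-scoped so every test sees the same fresh stream
    return np.random.default_rng(12345)
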