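import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from morphohet import synthetic

settings.register_profile(
    "repro",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")

SMALL_REGIONS = ("lh_cuneus", "Left-Thalamus")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_design():
    return synthetic.null_design(n_hc=10, n_et=12, region_names=SMALL_REGIONS, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_design):
    """A tiny reproducible null cohort: (morphometry, covariates, clinical)."""
    return synthetic.generate_cohort(small_design)
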