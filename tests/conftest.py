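import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from qbalin.regression import summary_from_published
from qbalin.synthetic import generate, preset

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

# The published summary statistics of the motivating cohort analysis:
# naive effect 2.21 kg/m^2 (95% CI 1.30, 3.11), n = 542, seven covariates.
BCG_SUMMARY = dict(
    estimate=2.21, ci_low=1.30, ci_high=3.11, conf_level=0.95, n=542, n_covariates=7
)


@pytest.fixture(scope="session")
def bcg_fit():
    return summary_from_published(**BCG_SUMMARY)


@pytest.fixture(scope="session")
def strong_data():
    """One strong-confounder cohort plus its truth record."""
    return generate(preset("strong_confounder"), seed=7)


@pytest.fixture(scope="session")
def bcg_like_data():
    return generate(preset("bcg_like"), seed=11)


def make_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
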