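import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 12-subject cohort shared by pipeline-level tests."""
    from eegstress import SimParams, simulate_cohort

    params = SimParams(
        n_subjects=12, duration_s=40.0, fs=125.0, effect_size=2.0, seed=7
    )
    return simulate_cohort(params)
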