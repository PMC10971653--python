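import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.filter_too_much],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240941)


@pytest.fixture
def small_cohort_config():
    """25 + 25 participants, zero measurement noise."""
    from hydrodensity.synthetic import CohortConfig, FEMALE_PROFILE, MALE_PROFILE

    from dataclasses import replace

    return CohortConfig(
        male=replace(MALE_PROFILE, n=25),
        female=replace(FEMALE_PROFILE, n=25),
        trial_noise_kg=0.0,
        girth_noise_mm=0.0,
        seed=7,
    )
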