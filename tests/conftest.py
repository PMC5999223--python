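import pytest
from hypothesis import HealthCheck, settings

from thymentropy import CohortConfig, fixture_case_table, simulate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixture_table():
    """The handcrafted boundary-probing mini slide table, loaded via the reader."""
    return fixture_case_table()


@pytest.fixture(scope="session")
def small_cohort():
    """A 20-case synthetic cohort with the default planted effect."""
    return simulate_cohort(CohortConfig(seed=7, n_cases=20))


@pytest.fixture(scope="session")
def null_cohort():
    """A 40-case synthetic cohort with no planted effects."""
    return simulate_cohort(CohortConfig(seed=11, n_cases=40).with_null_effects())
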