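import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_cohort():
    """One study-sized synthetic cohort (36 animals, 9 shams)."""
    from psofa.cohort import CohortConfig, generate_cohort

    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture(scope="session")
def default_labels(default_cohort):
    from psofa.pipeline import classify_cohort

    c = default_cohort
    return classify_cohort(c.monitoring, c.therapy, c.microbiology)
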