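import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from petadc import CohortSpec, PhantomSpec, analyze_cohort, generate_cohort, generate_phantom

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture(scope="session")
def default_phantom():
    """One default-parameter tumor phantom (deterministic)."""
    return generate_phantom(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def analyzed_cohort():
    """A default 17-patient synthetic cohort and its analyzed cohort table."""
    cohort = generate_cohort(CohortSpec(seed=7))
    table = analyze_cohort(cohort)
    return cohort, table
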