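import numpy as np
import pytest

from vo2ref.cohort import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def contaminated_cohort():
    """Synthetic registry cohort with a known 10% submaximal fraction."""
    spec = CohortSpec(n=5000, submaximal_fraction=0.1, seed=123)
    return spec, generate_cohort(spec)


@pytest.fixture(scope="session")
def clean_cohort():
    """Synthetic cohort with no injected submaximal records."""
    spec = CohortSpec(n=2000, seed=2024)
    return spec, generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
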