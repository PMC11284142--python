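import matplotlib
import numpy as np
import pytest
from hypothesis import settings

matplotlib.use("Agg")

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

from tibtorsion import CohortSpec, simulate_cohort  # noqa: E402


@pytest.fixture(scope="session")
def small_noisy_cohort():
    """10 subjects, 2 raters × 2 sessions, default 0.5 mm jitter."""
    return simulate_cohort(CohortSpec(n_subjects=10, seed=5))


@pytest.fixture(scope="session")
def clean_cohort():
    """30 subjects, single reading, no landmark jitter."""
    return simulate_cohort(
        CohortSpec(n_subjects=30, rater_noise_sd=0.0, raters=1, sessions=1, seed=9)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
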