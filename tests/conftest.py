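import numpy as np
import pytest

from landrisk import cohort


@pytest.fixture(scope="session")
def default_config() -> cohort.CohortConfig:
    return cohort.CohortConfig()


@pytest.fixture(scope="session")
def small_cohort(default_config):
    """One seeded default cohort reused across read-only tests."""
    return cohort.generate_summary_cohort(default_config, seed=1234)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def mean_trial():
    """A noiseless trial built from the calibration means."""
    row = dict(cohort.SUMMARY_MEANS)
    return row, cohort.generate_trial_waveforms(row, body_mass=81.93)
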