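import numpy as np
import pytest

from filmsense.pipeline import StudyConfig, run_study
from filmsense.synth import CohortConfig, SubjectParams


@pytest.fixture(scope="session")
def small_study():
    """One small end-to-end study (2 subjects, 80 Hz, 50-min analysis span)."""
    config = StudyConfig(
        cohort=CohortConfig(n_subjects=2, duration_min=50.0, fs=80.0, seed=7)
    )
    return config, run_study(config)


@pytest.fixture()
def quiet_subject():
    """A subject with no RR jitter, for noise-free ECG constructions."""
    return SubjectParams("S01", hr_baseline=60.0, hrv_sd=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
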