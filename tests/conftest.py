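import numpy as np
import pytest

from depthtms.datamodel import ProtocolParams, StudyConfig
from depthtms.spectral import derive_train_schedule
from depthtms.synth import CohortSimParams, EEGSimParams, simulate_cohort, simulate_eeg_session


@pytest.fixture(scope="session")
def config():
    return StudyConfig()


@pytest.fixture(scope="session")
def cohort200():
    """Two-arm cohort with the default planted interaction, no dropout."""
    params = CohortSimParams(n_per_arm=200, seed=0, dropout_prob=0.0)
    return simulate_cohort(params)


@pytest.fixture(scope="session")
def short_schedule():
    """15-train session schedule (330 s of the standard 18 Hz protocol)."""
    return derive_train_schedule(ProtocolParams(session_length=330.0))


@pytest.fixture(scope="session")
def treatment_session(short_schedule):
    params = EEGSimParams(seed=1, sampling_rate=250.0)
    return simulate_eeg_session(params, short_schedule)


@pytest.fixture(scope="session")
def resting_session():
    params = EEGSimParams(seed=2, sampling_rate=250.0, duration=120.0)
    return simulate_eeg_session(params, condition="resting")
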