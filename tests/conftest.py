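import numpy as np
import pytest

from lunghist import DetectionParams, ProgressionParams, SmokingConfig, SmokingHistory
from lunghist.tsce import PLACEHOLDER_RESPONSE


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)


@pytest.fixture
def pp():
    """Calibrated progression parameters (package defaults)."""
    return ProgressionParams()


@pytest.fixture
def dp():
    """Calibrated detection parameters (package defaults)."""
    return DetectionParams()


@pytest.fixture
def smoking_config():
    return SmokingConfig()


@pytest.fixture
def response():
    return PLACEHOLDER_RESPONSE


@pytest.fixture
def never_smoker():
    return SmokingHistory(
        sex="female",
        birth_year=1930,
        init_age=None,
        quit_age=None,
        intensity=0.0,
        other_cause_death_age=85.0,
    )


@pytest.fixture
def current_smoker():
    return SmokingHistory(
        sex="male",
        birth_year=1930,
        init_age=18.0,
        quit_age=None,
        intensity=1.5,
        other_cause_death_age=80.0,
    )


@pytest.fixture
def former_smoker():
    return SmokingHistory(
        sex="male",
        birth_year=1930,
        init_age=20.0,
        quit_age=40.0,
        intensity=1.0,
        other_cause_death_age=85.0,
    )
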