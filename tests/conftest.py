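from __future__ import annotations

import numpy as np
import pytest

from relcal.types import CalibrationSession, CalibrationStage, SubjectProfile


@pytest.fixture
def profile() -> SubjectProfile:
    """A subject with round HR anchors: reserve = 120 bpm."""
    return SubjectProfile(
        subject_id="P01", age=30, sex="M", height_cm=180, weight_kg=75,
        resting_hr=60, max_hr=180, vo2max=45.0,
    )


def make_line_session(
    profile: SubjectProfile,
    slope: float = 80.0,
    intercept: float = 300.0,
    hrr_targets=(15.0, 25.0, 35.0, 50.0, 65.0),
    minutes: int = 5,
) -> CalibrationSession:
    """A noise-free session whose stage points sit exactly on
    counts = slope·%HRR + intercept (constant within each stage)."""
    speeds = (3.2, 4.8, 6.4, 8.0, 9.6)
    stages = []
    for speed, hrr in zip(speeds, hrr_targets):
        hr = profile.resting_hr + hrr / 100.0 * profile.hr_reserve
        counts = slope * hrr + intercept
        stages.append(
            CalibrationStage(speed, [hr] * minutes, [counts] * minutes, minutes)
        )
    return CalibrationSession(profile, stages)


@pytest.fixture
def line_session(profile) -> CalibrationSession:
    return make_line_session(profile)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20130401)
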