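"""Domain types shared across the package.

Units follow exercise-physiology convention throughout: heart rates in
beats·min⁻¹, speeds in km·h⁻¹ (kph), VO2 in ml·kg⁻¹·min⁻¹, accelerometer
output in counts·min⁻¹ at 60-second epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Literal, Sequence

import numpy as np

from .exceptions import EmptySeriesError, InvalidProfileError

Sex = Literal["M", "F"]


@dataclass(frozen=True)
class SubjectProfile:
    """Physiological inputs for one subject.

    ``resting_hr`` and ``max_hr`` bound the heart-rate reserve
    (HRR = HRmax − HRrest); ``vo2max`` is the measured maximal oxygen
    consumption used only for fitness grouping and covariate analysis —
    the calibration itself is HR-based.
    """

    subject_id: str
    age: float
    sex: Sex
    height_cm: float
    weight_kg: float
    resting_hr: float
    max_hr: float
    vo2max: float

    def __post_init__(self) -> None:
        if self.max_hr <= self.resting_hr:
            raise InvalidProfileError(
                f"{self.subject_id}: max_hr ({self.max_hr}) must exceed "
                f"resting_hr ({self.resting_hr})"
            )
        if self.vo2max <= 0:
            raise InvalidProfileError(f"{self.subject_id}: vo2max must be > 0")
        if self.age < 18:
            raise InvalidProfileError(f"{self.subject_id}: age must be >= 18")
        if self.height_cm <= 0 or self.weight_kg <= 0:
            raise InvalidProfileError(
                f"{self.subject_id}: height and weight must be positive"
            )

    @property
    def hr_reserve(self) -> float:
        return self.max_hr - self.resting_hr

    @property
    def bmi(self) -> float:
        """Body-mass index, kg·m⁻²; derived, never stored."""
        return self.weight_kg / (self.height_cm / 100.0) ** 2

    @property
    def met_capacity(self) -> float:
        """Exercise capacity in METs (1 MET = 3.5 ml O2·kg⁻¹·min⁻¹)."""
        return self.vo2max / 3.5


@dataclass
class CalibrationStage:
    """One constant-speed treadmill stage with minute-level recordings."""

    speed_kph: float
    minute_hr: Sequence[float]
    minute_counts: Sequence[float]
    planned_minutes: int = 5

    def __post_init__(self) -> None:
        self.minute_hr = list(self.minute_hr)
        self.minute_counts = list(self.minute_counts)
        if len(self.minute_hr) != len(self.minute_counts):
            raise ValueError(
                f"stage at {self.speed_kph} kph: HR and count series lengths "
                f"differ ({len(self.minute_hr)} vs {len(self.minute_counts)})"
            )
        if any(c < 0 for c in self.minute_counts):
            raise ValueError(
                f"stage at {self.speed_kph} kph: negative activity counts"
            )

    @property
    def n_minutes(self) -> int:
        return len(self.minute_hr)


@dataclass
class CalibrationSession:
    """An ordered submaximal treadmill test for one subject."""

    subject: SubjectProfile
    stages: list[CalibrationStage]
    terminated_early: bool = False
    termination_reason: str = ""

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("a calibration session needs at least one stage")
        speeds = [s.speed_kph for s in self.stages]
        if any(b <= a for a, b in zip(speeds, speeds[1:])):
            raise ValueError("stage speeds must be strictly increasing")


@dataclass(frozen=True)
class StageSummary:
    """Steady-state summary of one stage: means of the last two recorded
    minutes, plus the implied percent heart-rate reserve.

    ``hrr_pct`` outside [0, 100] is legal (flagged via ``in_range``, never
    clipped) — it signals supra-threshold or sub-resting data.
    """

    speed_kph: float
    mean_hr: float
    mean_counts: float
    hrr_pct: float

    @property
    def in_range(self) -> bool:
        return 0.0 <= self.hrr_pct <= 100.0


@dataclass(frozen=True)
class CutpointPair:
    """Individualized count thresholds at two target %HRR intensities."""

    moderate_cut: float
    vigorous_cut: float
    moderate_pct: float = 40.0
    vigorous_pct: float = 60.0


@dataclass(frozen=True)
class CutpointScheme:
    """A named pair of count thresholds used for epoch classification."""

    name: str
    moderate_cut: float
    vigorous_cut: float
    provenance: Literal["absolute_freedson", "individualized", "custom"] = "custom"

    def __post_init__(self) -> None:
        if not (0 < self.moderate_cut < self.vigorous_cut):
            raise ValueError(
                f"scheme {self.name!r}: need 0 < moderate_cut < vigorous_cut, "
                f"got {self.moderate_cut} / {self.vigorous_cut}"
            )

    @classmethod
    def from_pair(cls, pair: CutpointPair, name: str = "individualized") -> "CutpointScheme":
        return cls(name, pair.moderate_cut, pair.vigorous_cut, "individualized")


#: The Freedson absolute cutpoints: moderate 1952–5724, vigorous >= 5725 counts·min⁻¹.
FREEDSON = CutpointScheme("freedson_absolute", 1952.0, 5725.0, "absolute_freedson")


@dataclass
class EpochSeries:
    """A uniformly-spaced activity-count series for one subject."""

    subject_id: str
    start_time: datetime
    counts: np.ndarray
    epoch_length_s: int = 60

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.size == 0:
            raise EmptySeriesError(f"{self.subject_id}: empty epoch series")
        if np.any(self.counts < 0):
            raise ValueError(f"{self.subject_id}: negative activity counts")
        if self.epoch_length_s <= 0:
            raise ValueError("epoch_length_s must be positive")

    @property
    def counts_per_minute(self) -> np.ndarray:
        """Counts rescaled to counts·min⁻¹ (identity at 60 s epochs)."""
        return self.counts * (60.0 / self.epoch_length_s)

    @property
    def minutes_per_epoch(self) -> float:
        return self.epoch_length_s / 60.0


@dataclass(frozen=True)
class IntensityProfile:
    """Minutes spent in each intensity band under one cutpoint scheme."""

    scheme: CutpointScheme
    minutes_light: float
    minutes_moderate: float
    minutes_vigorous: float

    @property
    def total_minutes(self) -> float:
        return self.minutes_light + self.minutes_moderate + self.minutes_vigorous

    @property
    def minutes_mvpa(self) -> float:
        return self.minutes_moderate + self.minutes_vigorous


@dataclass(frozen=True)
class FitnessGroup:
    """A fitness stratum defined on MET capacity (VO2max / 3.5)."""

    label: Literal["low", "moderate", "high"]
    met_lower: float
    met_upper: float


# <10 MET / 10–13 MET (closed) / >13 MET
LOW_FIT = FitnessGroup("low", 0.0, 10.0)
MODERATE_FIT = FitnessGroup("moderate", 10.0, 13.0)
HIGH_FIT = FitnessGroup("high", 13.0, float("inf"))
GROUPS = (LOW_FIT, MODERATE_FIT, HIGH_FIT)
GROUP_LABELS = ("low", "moderate", "high")
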