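"""Synthetic cohorts for the graded submaximal treadmill protocol.

The generator emulates the study conditions the method assumes: five
5-minute stages at 3.2/4.8/6.4/8.0/9.6 kph, walking below 8.0 kph and
running at or above it, with the test stopped at the first minute the
subject reaches 85% of measured HRmax.

Physiological model
-------------------
Oxygen demand follows the standard treadmill economy equations
(speed v in m·min⁻¹):

    walking:  VO2 = 0.1·v + 3.5      (below the run threshold)
    running:  VO2 = 0.2·v + 3.5      (at/above the run threshold)

The heart-rate response adopts the %HRR ≡ %VO2-reserve equivalence used in
exercise prescription: fractional reserve f = (VO2 − 3.5)/(VO2max − 3.5),
clipped to [0, 1.05], and HR = HRrest + f·(HRmax − HRrest) + noise. Fitter
subjects therefore sit at a lower %HRR at any speed.

Activity counts are fitness-independent and track *net metabolic demand*:

    counts = max(0, c0 + s_subj·(VO2demand − 3.5) + noise),

with a per-subject sensitivity s_subj (device placement/gait variability).
Because demand jumps at the walk→run transition, simulated counts jump with
it — the vertical-acceleration step real hip accelerometers show when a
subject starts running — which keeps each subject's counts-vs-%HRR relation
exactly linear across regimes. The implied true cutpoint at p% HRR has the
closed form c0 + s_subj·(VO2max − 3.5)·p/100, strictly increasing in VO2max.

Group parameters (VO2max, resting/max HR, age, weight, BMI, sex mix) follow
the reference cohort's three fitness strata. All randomness flows through a
single numpy Generator; identical seeds give identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import InvalidProfileError
from .types import (
    GROUP_LABELS,
    CalibrationSession,
    CalibrationStage,
    CutpointPair,
    FitnessGroup,
    SubjectProfile,
)

KPH_TO_M_PER_MIN = 1000.0 / 60.0
RESTING_VO2 = 3.5  # ml·kg⁻¹·min⁻¹, 1 MET


@dataclass(frozen=True)
class ProtocolSpec:
    """The graded treadmill protocol."""

    speeds_kph: tuple[float, ...] = (3.2, 4.8, 6.4, 8.0, 9.6)
    stage_minutes: int = 5
    termination_fraction_of_hrmax: float = 0.85
    run_threshold_kph: float = 8.0

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.speeds_kph, self.speeds_kph[1:])):
            raise ValueError("protocol speeds must be strictly increasing")
        if not 0 < self.termination_fraction_of_hrmax < 1:
            raise ValueError("termination fraction must lie in (0, 1)")


# (mean, sd) per group: low, moderate, high
_GROUP_VO2MAX = {"low": (31.6, 2.2), "moderate": (40.1, 2.7), "high": (51.2, 3.7)}
_GROUP_AGE = {"low": (28.8, 7.2), "moderate": (25.7, 5.7), "high": (25.8, 5.1)}
_GROUP_WEIGHT = {"low": (89.2, 22.6), "moderate": (73.3, 18.5), "high": (72.0, 12.1)}
_GROUP_BMI = {"low": (30.2, 5.1), "moderate": (24.8, 4.6), "high": (23.8, 3.0)}
_GROUP_MALE_FRACTION = {"low": 4 / 9, "moderate": 11 / 31, "high": 23 / 33}
_MET_BOUNDS = {"low": (0.0, 10.0), "moderate": (10.0, 13.0), "high": (13.0, np.inf)}


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-generator settings.

    Group sizes default to the reference cohort (9/31/33). Noise SDs are
    per recorded minute: 3 beats·min⁻¹ on HR, 150 counts·min⁻¹ on counts.
    ``counts_demand_slope_*`` parameterise the per-subject count sensitivity
    in counts·min⁻¹ per ml·kg⁻¹·min⁻¹ of net oxygen demand.
    """

    n_low: int = 9
    n_moderate: int = 31
    n_high: int = 33
    seed: int = 0
    protocol: ProtocolSpec = field(default_factory=ProtocolSpec)
    hr_noise_sd: float = 3.0
    counts_noise_sd: float = 150.0
    counts_demand_slope_mean: float = 300.0
    counts_demand_slope_sd: float = 30.0
    counts_intercept: float = -550.0
    resting_hr_mean: float = 62.0
    resting_hr_sd: float = 8.0
    max_hr_mean: float = 188.0
    max_hr_sd: float = 9.0
    min_hr_reserve: float = 60.0

    def __post_init__(self) -> None:
        for name in ("hr_noise_sd", "counts_noise_sd", "counts_demand_slope_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if min(self.n_low, self.n_moderate, self.n_high) < 0:
            raise ValueError("group sizes must be >= 0")

    def group_sizes(self) -> dict[str, int]:
        return {"low": self.n_low, "moderate": self.n_moderate, "high": self.n_high}


def metabolic_demand(speed_kph: float, protocol: ProtocolSpec | None = None) -> float:
    """Steady-state oxygen demand (ml·kg⁻¹·min⁻¹) at a treadmill speed."""
    protocol = protocol or ProtocolSpec()
    if speed_kph <= 0:
        raise ValueError("speed must be positive")
    v = speed_kph * KPH_TO_M_PER_MIN
    coef = 0.2 if speed_kph >= protocol.run_threshold_kph else 0.1
    return coef * v + RESTING_VO2


_MAX_REDRAWS = 100


def _truncated_normal(rng, mean, sd, lo, hi, what):
    for _ in range(_MAX_REDRAWS):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return float(x)
    raise RuntimeError(
        f"could not draw {what} in ({lo}, {hi}) after {_MAX_REDRAWS} attempts"
    )


def simulate_profile(
    group: FitnessGroup | str, rng: np.random.Generator, config: SimulationConfig | None = None,
    subject_id: str = "sim",
) -> SubjectProfile:
    """Draw one subject from a fitness stratum.

    VO2max is normal, truncated to the group's MET bounds; HR anchors are
    redrawn until HRmax − HRrest meets the minimum reserve; age is
    truncated at 18; height is derived from drawn weight and BMI.
    """
    config = config or SimulationConfig()
    label = group.label if isinstance(group, FitnessGroup) else group
    if label not in GROUP_LABELS:
        raise ValueError(f"unknown fitness group {label!r}")
    met_lo, met_hi = _MET_BOUNDS[label]
    vo2max = _truncated_normal(
        rng, *_GROUP_VO2MAX[label], met_lo * RESTING_VO2, met_hi * RESTING_VO2, "vo2max"
    )
    for _ in range(_MAX_REDRAWS):
        resting_hr = rng.normal(config.resting_hr_mean, config.resting_hr_sd)
        max_hr = rng.normal(config.max_hr_mean, config.max_hr_sd)
        if max_hr - resting_hr >= config.min_hr_reserve:
            break
    else:
        raise RuntimeError("could not draw HR anchors with sufficient reserve")
    age = _truncated_normal(rng, *_GROUP_AGE[label], 18.0, np.inf, "age")
    weight = _truncated_normal(rng, *_GROUP_WEIGHT[label], 35.0, np.inf, "weight")
    bmi = _truncated_normal(rng, *_GROUP_BMI[label], 15.0, np.inf, "bmi")
    height_cm = float(np.sqrt(weight / bmi) * 100.0)
    sex = "M" if rng.random() < _GROUP_MALE_FRACTION[label] else "F"
    return SubjectProfile(
        subject_id=subject_id,
        age=age,
        sex=sex,
        height_cm=height_cm,
        weight_kg=weight,
        resting_hr=float(resting_hr),
        max_hr=float(max_hr),
        vo2max=vo2max,
    )


def steady_state_response(
    profile: SubjectProfile,
    speed_kph: float,
    rng: np.random.Generator,
    config: SimulationConfig | None = None,
    counts_slope: float | None = None,
) -> tuple[float, float]:
    """One simulated minute at a treadmill speed: (HR, counts).

    ``counts_slope`` is the subject's count sensitivity; when omitted the
    configured mean is used (a noise-free call is then fully deterministic
    in the profile).
    """
    config = config or SimulationConfig()
    if profile.vo2max <= RESTING_VO2:
        raise InvalidProfileError("vo2max must exceed resting VO2 (3.5)")
    slope = config.counts_demand_slope_mean if counts_slope is None else counts_slope
    vo2 = metabolic_demand(speed_kph, config.protocol)
    frac = float(np.clip((vo2 - RESTING_VO2) / (profile.vo2max - RESTING_VO2), 0.0, 1.05))
    hr = profile.resting_hr + frac * profile.hr_reserve
    counts = config.counts_intercept + slope * (vo2 - RESTING_VO2)
    if config.hr_noise_sd > 0:
        hr += rng.normal(0.0, config.hr_noise_sd)
    if config.counts_noise_sd > 0:
        counts += rng.normal(0.0, config.counts_noise_sd)
    return float(hr), float(max(0.0, counts))


def simulate_session(
    profile: SubjectProfile,
    protocol: ProtocolSpec | None = None,
    rng: np.random.Generator | None = None,
    config: SimulationConfig | None = None,
    counts_slope: float | None = None,
) -> CalibrationSession:
    """Minute-by-minute simulated test, stopped at the first minute the
    heart rate reaches the termination fraction of HRmax (that minute is
    recorded, then the test ends)."""
    config = config or SimulationConfig()
    protocol = protocol or config.protocol
    if protocol is not config.protocol:
        config = replace(config, protocol=protocol)
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    threshold = protocol.termination_fraction_of_hrmax * profile.max_hr
    stages: list[CalibrationStage] = []
    terminated = False
    for speed in protocol.speeds_kph:
        hrs: list[float] = []
        counts: list[float] = []
        for _ in range(protocol.stage_minutes):
            hr, c = steady_state_response(profile, speed, rng, config, counts_slope)
            hrs.append(hr)
            counts.append(c)
            if hr >= threshold:
                terminated = True
                break
        stages.append(CalibrationStage(speed, hrs, counts, protocol.stage_minutes))
        if terminated:
            break
    reason = (
        f"reached {100 * protocol.termination_fraction_of_hrmax:.0f}% of HRmax"
        if terminated
        else ""
    )
    return CalibrationSession(profile, stages, terminated, reason)


def true_cutpoints(
    profile: SubjectProfile,
    counts_slope: float | None = None,
    config: SimulationConfig | None = None,
    moderate_pct: float = 40.0,
    vigorous_pct: float = 60.0,
) -> CutpointPair:
    """The generating model's exact cutpoints for a subject.

    Under the demand-linear counts model the noise-free counts-vs-%HRR
    relation is the line counts = c0 + s·(VO2max − 3.5)·(%HRR/100), so the
    true cutpoint at p% HRR is available in closed form.
    """
    config = config or SimulationConfig()
    slope = config.counts_demand_slope_mean if counts_slope is None else counts_slope
    reserve = profile.vo2max - RESTING_VO2
    if reserve <= 0:
        raise InvalidProfileError("vo2max must exceed resting VO2 (3.5)")

    def cut(pct: float) -> float:
        return config.counts_intercept + slope * reserve * pct / 100.0

    return CutpointPair(cut(moderate_pct), cut(vigorous_pct), moderate_pct, vigorous_pct)


@dataclass
class SimulatedSubject:
    """One simulated subject: profile, latent count sensitivity, the
    simulated session, and the generating model's true cutpoints."""

    profile: SubjectProfile
    group_label: str
    counts_slope: float
    session: CalibrationSession
    truth: CutpointPair

    def __iter__(self):
        # allow `(profile, session)` unpacking per the cohort contract
        return iter((self.profile, self.session))


def simulate_cohort(config: SimulationConfig | None = None) -> list[SimulatedSubject]:
    """Generate the full cohort (default 9 low / 31 moderate / 33 high).

    Deterministic in ``config.seed``: one Generator drives every draw in a
    fixed order.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    cohort: list[SimulatedSubject] = []
    idx = 0
    for label in GROUP_LABELS:
        for _ in range(config.group_sizes()[label]):
            idx += 1
            profile = simulate_profile(label, rng, config, subject_id=f"S{idx:03d}")
            slope = float(
                rng.normal(config.counts_demand_slope_mean, config.counts_demand_slope_sd)
            )
            session = simulate_session(profile, config.protocol, rng, config, slope)
            cohort.append(
                SimulatedSubject(
                    profile=profile,
                    group_label=label,
                    counts_slope=slope,
                    session=session,
                    truth=true_cutpoints(profile, slope, config),
                )
            )
    return cohort
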