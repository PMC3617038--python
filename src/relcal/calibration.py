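"""Individualized cutpoint calibration.

A subject walks/runs a graded submaximal treadmill protocol while wearing a
heart-rate monitor and a hip accelerometer. Each stage is reduced to a
steady-state point (mean of the last two recorded minutes) and expressed as
percent heart-rate reserve,

    %HRR = 100 · (HR_stage − HR_rest) / (HR_max − HR_rest).

An ordinary least-squares line through the last three achieved stages,
counts = m·%HRR + b, is then evaluated at 40% and 60% HRR to obtain the
subject's individualized moderate and vigorous count thresholds.

The fit is exposed statsmodels-style: :class:`CutpointCalibration` is the
model, its :meth:`~CutpointCalibration.fit` returns a :class:`CutpointModel`
results object carrying the estimates, diagnostics and a ``summary()`` table.
Thin functional wrappers (:func:`fit_cutpoint_model`, :func:`derive_cutpoints`,
:func:`calibrate_subject`) cover script use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import statsmodels.api as sm

from .exceptions import (
    CalibrationFailureError,
    InsufficientCalibrationDataError,
    InvalidProfileError,
    SingularFitError,
    StageUnusableError,
)
from .types import (
    CalibrationSession,
    CalibrationStage,
    CutpointPair,
    StageSummary,
    SubjectProfile,
)

Orientation = Literal["counts_on_hrr", "hrr_on_counts"]

#: Minutes averaged at the end of each stage to estimate steady state.
AVERAGING_MINUTES = 2
#: Stages entering each subject's regression (the last ones achieved).
N_CALIBRATION_STAGES = 3


@dataclass(frozen=True)
class CalibrationConfig:
    """Tunable knobs of the calibration pipeline.

    Defaults reproduce the reference protocol: last 3 achieved stages,
    last-2-minute averaging, counts regressed on %HRR, cutpoints at
    40% (moderate) and 60% (vigorous) HRR.
    """

    orientation: Orientation = "counts_on_hrr"
    moderate_pct: float = 40.0
    vigorous_pct: float = 60.0
    n_stages: int = N_CALIBRATION_STAGES
    averaging_minutes: int = AVERAGING_MINUTES

    def __post_init__(self) -> None:
        if not self.moderate_pct < self.vigorous_pct:
            raise ValueError("moderate_pct must be below vigorous_pct")
        if self.n_stages < 3:
            raise ValueError("need at least 3 stages per fit")


def hrr_percent(hr: float, hr_rest: float, hr_max: float) -> float:
    """Percent heart-rate reserve of ``hr`` given a subject's HR anchors.

    Returns ``100·(hr − hr_rest)/(hr_max − hr_rest)``. Values below 0 or
    above 100 are returned as-is; validity is the caller's call.
    """
    if hr_max <= hr_rest:
        raise InvalidProfileError(
            f"hr_max ({hr_max}) must exceed hr_rest ({hr_rest})"
        )
    return 100.0 * (hr - hr_rest) / (hr_max - hr_rest)


def stage_summary(stage: CalibrationStage, profile: SubjectProfile) -> StageSummary:
    """Summarise one stage: arithmetic means of the final two recorded
    minutes of HR and counts, and the %HRR implied by the mean HR."""
    if stage.n_minutes < AVERAGING_MINUTES:
        raise StageUnusableError(
            f"stage at {stage.speed_kph} kph has {stage.n_minutes} recorded "
            f"minute(s); need >= {AVERAGING_MINUTES}"
        )
    mean_hr = float(np.mean(stage.minute_hr[-AVERAGING_MINUTES:]))
    mean_counts = float(np.mean(stage.minute_counts[-AVERAGING_MINUTES:]))
    pct = hrr_percent(mean_hr, profile.resting_hr, profile.max_hr)
    return StageSummary(stage.speed_kph, mean_hr, mean_counts, pct)


def select_calibration_stages(
    session: CalibrationSession, n_stages: int = N_CALIBRATION_STAGES
) -> list[CalibrationStage]:
    """The last ``n_stages`` usable stages achieved before termination.

    A stage is usable when it recorded at least two minutes (a stage
    truncated at its first minute by the 85% HRmax stop is dropped).
    """
    usable = [s for s in session.stages if s.n_minutes >= AVERAGING_MINUTES]
    if len(usable) < n_stages:
        raise InsufficientCalibrationDataError(
            f"{session.subject.subject_id}: {len(usable)} usable stage(s), "
            f"need >= {n_stages}"
        )
    return usable[-n_stages:]


@dataclass(frozen=True)
class CutpointModel:
    """Results of a fitted counts–%HRR line.

    ``slope``/``intercept`` are in the units of the chosen orientation:
    counts·min⁻¹ per %HRR for ``counts_on_hrr`` (the default), %HRR per
    count·min⁻¹ for ``hrr_on_counts``. ``residual_sd`` is in
    dependent-variable units (ddof = 2). A negative slope is physiologically
    implausible and is carried as a warning; :meth:`predict_cutpoint` then
    refuses to produce thresholds.
    """

    slope: float
    intercept: float
    orientation: Orientation
    r_squared: float
    residual_sd: float
    n_points: int
    slope_se: float = float("nan")
    intercept_se: float = float("nan")
    warnings: tuple[str, ...] = ()

    def predict_cutpoint(self, pct: float) -> float:
        """The counts·min⁻¹ threshold at a target %HRR."""
        if self.slope < 0:
            raise CalibrationFailureError(
                "negative slope: counts decrease with %HRR; calibration failed"
            )
        if self.orientation == "counts_on_hrr":
            cut = self.slope * pct + self.intercept
        else:
            if self.slope == 0:
                raise ZeroDivisionError(
                    "hrr_on_counts orientation with zero slope cannot be inverted"
                )
            cut = (pct - self.intercept) / self.slope
        if not np.isfinite(cut) or cut <= 0:
            raise CalibrationFailureError(
                f"derived cutpoint at {pct}% HRR is non-positive ({cut:.1f} "
                "counts·min⁻¹); calibration failed"
            )
        return float(cut)

    def derive_cutpoints(
        self, moderate_pct: float = 40.0, vigorous_pct: float = 60.0
    ) -> CutpointPair:
        if not moderate_pct < vigorous_pct:
            raise ValueError("moderate_pct must be below vigorous_pct")
        return CutpointPair(
            self.predict_cutpoint(moderate_pct),
            self.predict_cutpoint(vigorous_pct),
            moderate_pct,
            vigorous_pct,
        )

    def summary(self) -> str:
        dep, reg = (
            ("counts·min⁻¹", "%HRR")
            if self.orientation == "counts_on_hrr"
            else ("%HRR", "counts·min⁻¹")
        )
        lines = [
            "Individualized cutpoint calibration",
            "=" * 46,
            f"{'Dep. variable:':<22}{dep}",
            f"{'Regressor:':<22}{reg}",
            f"{'No. stage points:':<22}{self.n_points}",
            f"{'slope':<12}{self.slope:>12.4f}  (SE {self.slope_se:.4f})",
            f"{'intercept':<12}{self.intercept:>12.4f}  (SE {self.intercept_se:.4f})",
            f"{'R-squared:':<22}{self.r_squared:.4f}",
            f"{'Residual SD:':<22}{self.residual_sd:.2f}",
        ]
        for w in self.warnings:
            lines.append(f"WARNING: {w}")
        return "\n".join(lines)


class CutpointCalibration:
    """Per-subject linear model relating activity counts and %HRR.

    Parameters
    ----------
    summaries
        Steady-state stage summaries (typically the last three stages).
    orientation
        ``counts_on_hrr`` regresses counts on %HRR (default; predicts the
        count threshold at a target intensity). ``hrr_on_counts`` fits the
        reverse regression and inverts it algebraically; the two agree only
        when r² = 1.
    """

    def __init__(
        self,
        summaries: Sequence[StageSummary],
        orientation: Orientation = "counts_on_hrr",
    ):
        if len(summaries) < 3:
            raise InsufficientCalibrationDataError(
                f"need >= 3 stage summaries, got {len(summaries)}"
            )
        if orientation not in ("counts_on_hrr", "hrr_on_counts"):
            raise ValueError(f"unknown orientation {orientation!r}")
        self.summaries = list(summaries)
        self.orientation: Orientation = orientation
        hrr = np.array([s.hrr_pct for s in self.summaries], dtype=float)
        counts = np.array([s.mean_counts for s in self.summaries], dtype=float)
        if orientation == "counts_on_hrr":
            self.exog, self.endog = hrr, counts
        else:
            self.exog, self.endog = counts, hrr

    @classmethod
    def from_session(
        cls,
        session: CalibrationSession,
        orientation: Orientation = "counts_on_hrr",
        n_stages: int = N_CALIBRATION_STAGES,
    ) -> "CutpointCalibration":
        stages = select_calibration_stages(session, n_stages)
        summaries = [stage_summary(s, session.subject) for s in stages]
        return cls(summaries, orientation)

    def fit(self) -> CutpointModel:
        x, y = self.exog, self.endog
        if np.ptp(x) == 0:
            raise SingularFitError(
                "regressor has zero variance; cannot fit a line"
            )
        res = sm.OLS(y, sm.add_constant(x)).fit()
        intercept, slope = (float(v) for v in res.params)
        n = len(y)
        ssr = float(res.ssr)
        tss = float(np.sum((y - y.mean()) ** 2))
        # centred TSS of 0 with ~0 residual is a perfect (flat) fit
        r2 = 1.0 - ssr / tss if tss > 0 else (1.0 if ssr < 1e-12 else 0.0)
        resid_sd = float(np.sqrt(ssr / (n - 2))) if n > 2 else float("nan")
        warnings: tuple[str, ...] = ()
        if slope < 0:
            warnings = (
                "negative slope: counts decrease with intensity "
                "(calibration failure)",
            )
        return CutpointModel(
            slope=slope,
            intercept=intercept,
            orientation=self.orientation,
            r_squared=float(np.clip(r2, 0.0, 1.0)),
            residual_sd=resid_sd,
            n_points=n,
            slope_se=float(res.bse[1]),
            intercept_se=float(res.bse[0]),
            warnings=warnings,
        )


def fit_cutpoint_model(
    summaries: Sequence[StageSummary],
    orientation: Orientation = "counts_on_hrr",
) -> CutpointModel:
    """Fit the counts–%HRR line through a set of stage summaries."""
    return CutpointCalibration(summaries, orientation).fit()


def derive_cutpoints(
    model: CutpointModel, moderate_pct: float = 40.0, vigorous_pct: float = 60.0
) -> CutpointPair:
    """Evaluate (or invert) a fitted line at the two target intensities."""
    return model.derive_cutpoints(moderate_pct, vigorous_pct)


@dataclass
class CalibrationReport:
    """Everything produced by calibrating one subject: the selected stage
    summaries, the fitted model and the derived cutpoint pair."""

    subject: SubjectProfile
    summaries: list[StageSummary]
    model: CutpointModel
    cutpoints: CutpointPair

    def __iter__(self):
        # allow `model, pair = calibrate_subject(...)` unpacking
        return iter((self.model, self.cutpoints))

    def summary(self) -> str:
        head = [
            f"Subject {self.subject.subject_id} "
            f"(HRrest {self.subject.resting_hr:.0f}, HRmax {self.subject.max_hr:.0f}, "
            f"VO2max {self.subject.vo2max:.1f} ml·kg⁻¹·min⁻¹)",
            f"{'speed_kph':>9} {'mean_hr':>8} {'mean_counts':>12} {'hrr_pct':>8}",
        ]
        for s in self.summaries:
            head.append(
                f"{s.speed_kph:>9.1f} {s.mean_hr:>8.1f} "
                f"{s.mean_counts:>12.1f} {s.hrr_pct:>8.1f}"
            )
        head.append(self.model.summary())
        head.append(
            f"moderate cut ({self.cutpoints.moderate_pct:.0f}% HRR): "
            f"{self.cutpoints.moderate_cut:.0f} counts·min⁻¹"
        )
        head.append(
            f"vigorous cut ({self.cutpoints.vigorous_pct:.0f}% HRR): "
            f"{self.cutpoints.vigorous_cut:.0f} counts·min⁻¹"
        )
        return "\n".join(head)


def calibrate_subject(
    session: CalibrationSession, config: CalibrationConfig | None = None
) -> CalibrationReport:
    """Run the full pipeline for one subject: select the last stages,
    summarise them, fit the line and derive the cutpoint pair.

    Raises the underlying error, annotated with the subject id, if any
    step fails.
    """
    cfg = config or CalibrationConfig()
    sid = session.subject.subject_id
    try:
        stages = select_calibration_stages(session, cfg.n_stages)
        summaries = [stage_summary(s, session.subject) for s in stages]
        model = CutpointCalibration(summaries, cfg.orientation).fit()
        pair = model.derive_cutpoints(cfg.moderate_pct, cfg.vigorous_pct)
    except (
        InsufficientCalibrationDataError,
        StageUnusableError,
        SingularFitError,
        CalibrationFailureError,
    ) as err:
        raise type(err)(f"subject {sid}: {err}") from err
    return CalibrationReport(session.subject, summaries, model, pair)
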