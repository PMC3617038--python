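"""Calibration pipeline: %HRR arithmetic, stage selection and summarising,
the least-squares fit, and cutpoint derivation."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from relcal.calibration import (
    CalibrationConfig,
    CutpointCalibration,
    calibrate_subject,
    derive_cutpoints,
    fit_cutpoint_model,
    hrr_percent,
    select_calibration_stages,
    stage_summary,
)
from relcal.exceptions import (
    CalibrationFailureError,
    InsufficientCalibrationDataError,
    InvalidProfileError,
    SingularFitError,
    StageUnusableError,
)
from relcal.types import CalibrationSession, CalibrationStage, StageSummary

from _oracles import grid_search_ols
from conftest import make_line_session


def make_summaries(hrr, counts):
    return [StageSummary(3.2 + 1.6 * i, 100.0, c, h) for i, (h, c) in enumerate(zip(hrr, counts))]


class TestHrrPercent:
    @pytest.mark.parametrize(
        "hr, expected",
        [(60, 0.0), (180, 100.0), (120, 50.0), (90, 25.0), (186, 105.0), (48, -10.0)],
    )
    def test_examples(self, hr, expected):
        assert hrr_percent(hr, 60, 180) == pytest.approx(expected)

    def test_invalid_anchors_raise(self):
        with pytest.raises(InvalidProfileError):
            hrr_percent(120, 180, 180)

    @settings(derandomize=True, max_examples=50)
    @given(
        rest=st.floats(40, 90),
        reserve=st.floats(30, 150),
        frac=st.floats(0, 1),
    )
    def test_rest_and_max_anchor_the_scale(self, rest, reserve, frac):
        hr_max = rest + reserve
        assert hrr_percent(rest, rest, hr_max) == 0.0
        assert hrr_percent(hr_max, rest, hr_max) == pytest.approx(100.0)
        hr = rest + frac * reserve
        assert hrr_percent(hr, rest, hr_max) == pytest.approx(100 * frac, abs=1e-9)


class TestStageSummary:
    @pytest.mark.parametrize(
        "hr, counts, mean_hr, mean_counts",
        [
            ([110, 118, 122, 124, 126], [3000, 3100, 3200, 3300, 3400], 125.0, 3350.0),
            ([120] * 5, [2000] * 5, 120.0, 2000.0),
            ([110, 118], [1000, 1200], 114.0, 1100.0),  # truncated stage
        ],
    )
    def test_last_two_minute_means(self, profile, hr, counts, mean_hr, mean_counts):
        s = stage_summary(CalibrationStage(6.4, hr, counts), profile)
        assert s.mean_hr == pytest.approx(mean_hr)
        assert s.mean_counts == pytest.approx(mean_counts)
        assert s.hrr_pct == pytest.approx(hrr_percent(mean_hr, 60, 180))

    def test_single_minute_stage_unusable(self, profile):
        with pytest.raises(StageUnusableError):
            stage_summary(CalibrationStage(6.4, [120], [2000]), profile)

    def test_out_of_range_hrr_flagged_not_clipped(self, profile):
        s = stage_summary(CalibrationStage(9.6, [190, 192], [8000, 8200]), profile)
        assert s.hrr_pct > 100 and not s.in_range


class TestStageSelection:
    def test_five_completed_stages_keep_last_three(self, line_session):
        selected = select_calibration_stages(line_session)
        assert [s.speed_kph for s in selected] == [6.4, 8.0, 9.6]

    def test_exactly_three_stages_all_kept(self, profile):
        session = make_line_session(profile, hrr_targets=(15, 25, 35))
        session = CalibrationSession(profile, session.stages[:3])
        assert [s.speed_kph for s in select_calibration_stages(session)] == [3.2, 4.8, 6.4]

    def test_single_minute_terminal_stage_dropped_before_selection(self, profile):
        full = make_line_session(profile).stages[:3]
        partial = CalibrationStage(8.0, [176], [5500])
        session = CalibrationSession(profile, full + [partial], terminated_early=True)
        assert [s.speed_kph for s in select_calibration_stages(session)] == [3.2, 4.8, 6.4]

    def test_two_stages_insufficient(self, profile):
        session = make_line_session(profile)
        session = CalibrationSession(profile, session.stages[:2])
        with pytest.raises(InsufficientCalibrationDataError):
            select_calibration_stages(session)


class TestFit:
    def test_noise_free_line_recovered_exactly(self):
        summaries = make_summaries([20, 40, 60], [80 * h + 300 for h in (20, 40, 60)])
        model = fit_cutpoint_model(summaries)
        assert model.slope == pytest.approx(80.0)
        assert model.intercept == pytest.approx(300.0)
        assert model.r_squared == pytest.approx(1.0)
        assert model.n_points == 3

    def test_three_point_fit_matches_frozen_normal_equations(self):
        # hand solution: Sxy=40500, Sxx=450 -> slope 90; 3800 - 90*45 = -250
        model = fit_cutpoint_model(make_summaries([30, 45, 60], [2500, 3700, 5200]))
        assert model.slope == pytest.approx(90.0, rel=1e-9)
        assert model.intercept == pytest.approx(-250.0, rel=1e-6)

    @pytest.mark.parametrize("seed", range(12))
    @pytest.mark.parametrize("n_points", [3, 4, 5])
    def test_fit_matches_grid_search_oracle(self, seed, n_points):
        rng = np.random.default_rng(seed * 100 + n_points)
        hrr = np.sort(rng.uniform(10, 80, n_points))
        hrr += np.linspace(0, 1, n_points)  # guard against near-ties
        counts = rng.uniform(20, 120) * hrr + rng.uniform(-2000, 2000)
        counts += rng.normal(0, 300, n_points)
        counts = np.maximum(counts, 1.0)
        model = fit_cutpoint_model(make_summaries(hrr, counts))
        slope_o, intercept_o = grid_search_ols(hrr, counts)
        assert model.slope == pytest.approx(slope_o, rel=1e-3, abs=1e-3)
        assert model.intercept == pytest.approx(intercept_o, rel=1e-3, abs=1e-2)

    def test_zero_variance_regressor_is_singular(self):
        with pytest.raises(SingularFitError):
            fit_cutpoint_model(make_summaries([40, 40, 40], [2500, 3700, 5200]))

    def test_negative_slope_flagged_and_refused(self):
        model = fit_cutpoint_model(make_summaries([20, 40, 60], [5000, 4000, 3000]))
        assert model.slope < 0 and model.warnings
        with pytest.raises(CalibrationFailureError):
            model.derive_cutpoints()

    def test_residual_sd_and_se_reported(self):
        rng = np.random.default_rng(5)
        hrr = np.array([20.0, 35, 50, 65, 80])
        counts = 70 * hrr + 500 + rng.normal(0, 200, 5)
        model = fit_cutpoint_model(make_summaries(hrr, counts))
        assert model.residual_sd > 0 and np.isfinite(model.slope_se)
        assert 0 <= model.r_squared < 1


class TestDeriveCutpoints:
    def test_linear_evaluation_at_40_and_60(self):
        model = fit_cutpoint_model(make_summaries([20, 40, 60], [80 * h + 300 for h in (20, 40, 60)]))
        pair = derive_cutpoints(model)
        assert pair.moderate_cut == pytest.approx(3500.0)
        assert pair.vigorous_cut == pytest.approx(5100.0)

    def test_inverse_orientation_agrees_when_r2_is_one(self):
        hrr = [20.0, 40.0, 60.0]
        counts = [80 * h + 300 for h in hrr]
        inv = fit_cutpoint_model(make_summaries(hrr, counts), "hrr_on_counts")
        # algebraic inverse of counts = 80·hrr + 300
        assert inv.slope == pytest.approx(0.0125)
        assert inv.intercept == pytest.approx(-3.75)
        pair = derive_cutpoints(inv)
        assert pair.moderate_cut == pytest.approx(3500.0)
        assert pair.vigorous_cut == pytest.approx(5100.0)

    def test_orientations_disagree_when_r2_below_one(self):
        rng = np.random.default_rng(7)
        hrr = np.array([20.0, 35, 50, 65])
        counts = 80 * hrr + 300 + rng.normal(0, 400, 4)
        fwd = derive_cutpoints(fit_cutpoint_model(make_summaries(hrr, counts)))
        inv = derive_cutpoints(
            fit_cutpoint_model(make_summaries(hrr, counts), "hrr_on_counts")
        )
        assert fwd.moderate_cut != pytest.approx(inv.moderate_cut, rel=1e-6)

    def test_noisy_fit_cutpoints_match_oracle_prediction(self):
        hrr, counts = [30.0, 45.0, 60.0], [2500.0, 3700.0, 5200.0]
        pair = derive_cutpoints(fit_cutpoint_model(make_summaries(hrr, counts)))
        slope_o, intercept_o = grid_search_ols(hrr, counts)
        assert pair.moderate_cut == pytest.approx(slope_o * 40 + intercept_o, rel=1e-3)
        assert pair.vigorous_cut == pytest.approx(slope_o * 60 + intercept_o, rel=1e-3)

    def test_strictly_increasing_in_pct_with_spacing_20_slope(self):
        model = fit_cutpoint_model(make_summaries([30, 45, 60], [2500, 3700, 5200]))
        pair = model.derive_cutpoints(40, 60)
        assert pair.vigorous_cut > pair.moderate_cut
        assert pair.vigorous_cut - pair.moderate_cut == pytest.approx(20 * model.slope)
        lower = model.derive_cutpoints(30, 40)
        assert lower.moderate_cut < pair.moderate_cut

    def test_non_positive_cutpoint_is_calibration_failure(self):
        model = fit_cutpoint_model(make_summaries([60, 70, 80], [100, 600, 1100]))
        with pytest.raises(CalibrationFailureError):
            model.derive_cutpoints(1, 60)  # extrapolates below zero counts

    def test_zero_slope_inverse_orientation_division_error(self):
        flat = fit_cutpoint_model(
            make_summaries([40.0, 40.0, 40.0], [2000.0, 3000.0, 4000.0]), "hrr_on_counts"
        )
        assert flat.slope == pytest.approx(0.0)
        with pytest.raises(ZeroDivisionError):
            flat.derive_cutpoints()


class TestCalibrateSubject:
    def test_end_to_end_recovers_generating_line(self, line_session):
        report = calibrate_subject(line_session)
        assert report.cutpoints.moderate_cut == pytest.approx(80 * 40 + 300, rel=1e-12)
        assert report.cutpoints.vigorous_cut == pytest.approx(80 * 60 + 300, rel=1e-12)
        assert report.model.r_squared == pytest.approx(1.0)

    def test_session_terminating_in_stage_four_uses_stages_two_to_four(self, profile):
        stages = make_line_session(profile).stages[:4]
        stages[3] = CalibrationStage(
            8.0, stages[3].minute_hr[:3], stages[3].minute_counts[:3]
        )
        session = CalibrationSession(profile, stages, terminated_early=True)
        report = calibrate_subject(session)
        assert [s.speed_kph for s in report.summaries] == [4.8, 6.4, 8.0]

    def test_two_stage_session_raises_with_subject_context(self, profile):
        session = CalibrationSession(profile, make_line_session(profile).stages[:2])
        with pytest.raises(InsufficientCalibrationDataError, match="P01"):
            calibrate_subject(session)

    def test_custom_target_percentages(self, line_session):
        cfg = CalibrationConfig(moderate_pct=30.0, vigorous_pct=40.0)
        report = calibrate_subject(line_session, cfg)
        assert report.cutpoints.moderate_cut == pytest.approx(80 * 30 + 300)
        assert report.cutpoints.vigorous_cut == pytest.approx(80 * 40 + 300)

    def test_summary_is_printable(self, line_session):
        text = calibrate_subject(line_session).summary()
        assert "slope" in text and "moderate cut" in text and "P01" in text


def test_model_results_shape(line_session):
    """The model/results split: CutpointCalibration.fit() returns the
    results object and the report unpacks to (model, cutpoints)."""
    model = CutpointCalibration.from_session(line_session).fit()
    assert model.n_points == 3
    result_model, pair = calibrate_subject(line_session)
    assert result_model.slope == pytest.approx(model.slope)
    assert pair.moderate_cut == pytest.approx(model.derive_cutpoints().moderate_cut)
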