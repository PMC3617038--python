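# Methods

## The calibration model

`relcal` treats intensity classification as a per-subject measurement
problem. The observable is the minute-epoch activity count of a hip-worn
accelerometer; the latent quantity of interest is relative intensity,
expressed as percent heart-rate reserve (%HRR). During a graded treadmill
test both are observed simultaneously, and over the submaximal range the
relation between them is well approximated by a line. The calibration
model is therefore ordinary least squares on three steady-state points:

    counts_i = m · %HRR_i + b + ε_i,        i = 1..3,

with %HRR = 100·(HR_stage − HR_rest)/(HR_max − HR_rest). The individualized
cutpoints are point predictions of this line at 40% HRR (moderate) and 60%
HRR (vigorous).

Assumptions, and what happens when they fail:

* **Linearity over the fitted range.** The three calibration points span
  roughly 20–75% HRR for most subjects; cutpoints at 40/60% are usually
  interpolations or short extrapolations. Strong nonlinearity (e.g. count
  saturation at sprinting speeds) is outside the fitted range by design.
* **Positive slope.** Counts must increase with intensity. A negative
  fitted slope is carried on the results object as a warning and cutpoint
  prediction then fails loudly (`CalibrationFailureError`) rather than
  returning implausible thresholds. Non-positive predicted cutpoints fail
  the same way.
* **Steady state.** Each stage is summarised by the mean of its last two
  recorded minutes; a stage with fewer than two minutes (typically the
  stage in which the 85% HRmax stop fired) is dropped before the last-3
  selection. Fewer than three usable stages is a refusal
  (`InsufficientCalibrationDataError`), never an extrapolated 2-point fit.

### Regression orientation

The quantity of interest is a *count* threshold at a fixed %HRR, so counts
are the dependent variable by default (`counts_on_hrr`). The reverse
orientation (`hrr_on_counts`, inverted algebraically as
cut = (pct − b)/m) is available because both conventions exist in the
field's reporting; the two agree exactly when r² = 1 and otherwise differ
by regression-to-the-mean. Tests assert both facts. Choosing the reverse
orientation changes every downstream number, so it is a config option, not
a heuristic.

### Key parameters

| parameter | default | units | why |
|---|---|---|---|
| moderate / vigorous targets | 40 / 60 | %HRR | standard relative-intensity band edges; configurable because high-fit subjects cross absolute thresholds near 30–40% HRR |
| stages per fit | 3 | — | the last three achieved stages; minimum for a line with a residual degree of freedom |
| averaging window | 2 | min | end-of-stage steady-state mean |
| termination | 0.85 | × HRmax | submaximal safety stop; also the mechanism that truncates low-fit sessions |
| absolute scheme | 1952 / 5725 | counts·min⁻¹ | the conventional moderate/vigorous thresholds used for comparison |

Band edges are lower-inclusive everywhere (moderate = [1952, 5724]),
matching the printed integer band of the absolute scheme, and applied
identically to individualized schemes. Epochs other than 60 s are rescaled
to counts·min⁻¹ before thresholding.

## Cohort analysis

MET capacity = VO2max/3.5 partitions subjects into <10 / 10–13 / >13 MET
groups; both boundary values (10 and 13 MET) fall in the middle group, the
only reading consistent with the interval labels. Group cutpoints use the
n−1 sample SD. The omnibus test is a one-way ANOVA; post-hoc contrasts are
pairwise Welch t-tests with Bonferroni adjustment over the three pairs — a
deliberately conservative procedure chosen because it is exactly
reproducible without reference to studentised-range tables, and because
group variances are not assumed equal. Covariate associations are squared
Pearson correlations between a cutpoint and VO2max, age, or BMI
(BMI = weight/height², derived, never stored).

## The synthetic-data generator

The generator exists so that every operation is testable end-to-end with
no device data. It emulates the calibration protocol, not free living.

* **Profiles.** VO2max is normal per group — (31.6, 2.2), (40.1, 2.7),
  (51.2, 3.7) ml·kg⁻¹·min⁻¹ for low/moderate/high fitness — truncated to
  the group's MET bounds. Resting and maximal HR are N(62, 8) and
  N(188, 9) bpm with reserve ≥ 60 enforced by redraw. Age, weight and BMI
  are drawn per group (height derived from weight and BMI); sex follows
  each group's male fraction. Group sizes default to 9/31/33.
* **Heart rate.** Oxygen demand follows the standard treadmill economy
  equations — walking 0.1·v + 3.5, running 0.2·v + 3.5 ml·kg⁻¹·min⁻¹
  (v in m·min⁻¹) — with the walk→run switch at 8.0 kph (configurable).
  The fractional reserve f = (VO2 − 3.5)/(VO2max − 3.5), clipped to
  [0, 1.05], maps to HR via the %HRR ≡ %VO2R equivalence,
  HR = HRrest + f·(HRmax − HRrest) + N(0, 3). The equivalence is a
  standard exercise-prescription approximation adopted here as a modelling
  assumption, not a claim about any particular dataset.
* **Counts.** counts = max(0, c0 + s·(VO2demand − 3.5) + N(0, 150)), with
  c0 = −550 counts·min⁻¹ and a per-subject sensitivity s ~ N(300, 30)
  counts·min⁻¹ per ml·kg⁻¹·min⁻¹. Counts depend only on the *work being
  done*, never on the subject's fitness — so any between-group cutpoint
  difference arises purely from the heart-rate side, which is the
  mechanism the method is built on. Making counts proportional to demand
  (rather than to treadmill speed) means counts jump at the walk→run
  transition exactly when %HRR does, mirroring the step in vertical
  acceleration when a subject starts running. Two consequences matter:
  each subject's noise-free counts-vs-%HRR relation is *exactly* linear
  across the transition, with closed-form true cutpoints
  c0 + s·(VO2max − 3.5)·pct/100 (used as ground truth in recovery tests);
  and expected cutpoints increase strictly with VO2max regardless of which
  stages a subject completes. A speed-linear counts model does not have
  either property once the 85% HRmax stop assigns different stage sets to
  different fitness groups: the heart-rate jump at the run transition then
  flattens mixed-stage fits and can invert the group ordering outright,
  which is physiologically backwards. Default magnitudes were chosen once
  to put simulated cutpoints in a realistic range (noise-free group means
  ≈ 2800/3850/5150 counts·min⁻¹ at 40% HRR); no acceptance check depends
  on absolute count magnitudes.
* **Termination.** Minutes are simulated i.i.d. around stage steady state
  (no on-transient — a documented simplification; the generator has no
  within-stage HR kinetics). The session stops at the first minute with
  HR ≥ 0.85·HRmax; that minute is recorded. Under the defaults, low-fit
  subjects typically stop in the first minute of the 8.0 kph stage and
  calibrate on the three walking stages, while high-fit subjects complete
  all five — reproducing the heterogeneous stage combinations a real
  graded protocol produces. (Real cohorts also report stage sets that skip
  an intermediate speed; a last-3-achieved rule cannot produce those, and
  the generator does not emulate them.)

What passing tests on this generator do **not** show: robustness to count
saturation at high running speeds, HR drift within stages, day-to-day HR
variability, device nonwear, or free-living intermittent activity. The
generator is a test harness for the pipeline's statistics, not a gait
model.

## Numerical choices

* OLS is delegated to statsmodels; a zero-variance regressor raises
  `SingularFitError` before fitting. r² is computed from centred sums of
  squares, defined as 1.0 for an exactly flat perfect fit, and clipped to
  [0, 1] against floating-point drift. Residual SD uses ddof = 2.
* %HRR values outside [0, 100] are flagged (`StageSummary.in_range`),
  never clipped — a supra-threshold final stage is real data.
* Tests compare the OLS path against an iteratively-zoomed grid-search
  least-squares oracle (centred parameterisation, 9 rounds of a 41×41
  grid), and the ANOVA/SD/r² paths against explicit sums-of-squares
  recomputations.
* Simulation problem sizes used by the test suite and the acceptance
  script — a 73-subject default cohort, 200 subjects for parameter
  recovery, 100 seeded cohorts for the ordering check, 1000 randomized
  epoch series for classification invariants — were chosen as the smallest
  sizes at which the Monte-Carlo checks are stable; the full suite runs in
  well under a minute.

## Known limitations

* Measured HRmax and VO2max are required inputs; no age-predicted HRmax
  helper is provided, because substituting 220 − age changes every %HRR
  value and silently redefines the cutpoints.
* The calibration is HR-based only; a %VO2-reserve calibration against
  measured gas exchange would be the validating gold standard and is out
  of scope.
* Pairwise Bonferroni over three groups is conservative; with more strata
  a less blunt multiplicity correction would be preferable.
* The device-export epoch dialect is a versioned, documented format in the
  spirit of ActiLife exports, not a bit-faithful reimplementation of any
  ActiLife release.
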