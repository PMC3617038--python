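# relcal

Individualized accelerometer cutpoints from submaximal heart-rate
calibration.

Fixed accelerometer thresholds — most commonly the Freedson cutpoints,
moderate 1952–5724 and vigorous ≥ 5725 counts·min⁻¹ — define physical-
activity intensity in absolute terms, regardless of how fit the wearer is.
For an unfit adult, 60% of heart-rate reserve may correspond to counts that
never reach the absolute vigorous threshold; for a very fit adult the
absolute threshold is crossed at an intensity that is only light-to-moderate
*for them*. `relcal` implements the individualized alternative: calibrate
each subject's own counts-per-intensity relation from a short graded
treadmill test, and classify their free-living epochs against thresholds
expressed relative to their capacity.

It is written for exercise physiologists and physical-activity researchers
who have a treadmill, a heart-rate monitor and a hip accelerometer.

## The method

For each subject, a graded submaximal treadmill test (5-minute stages at
3.2, 4.8, 6.4, 8.0, 9.6 kph, stopped when heart rate first reaches 85% of
measured HRmax) yields per-stage steady-state points. Each of the last three
achieved stages is summarised by the mean of its final two recorded minutes
and expressed as percent heart-rate reserve,

```
%HRR = 100 · (HR_stage − HR_rest) / (HR_max − HR_rest),
```

and an ordinary least-squares line

```
counts = m · %HRR + b
```

is fitted through the three points. The individualized moderate and
vigorous cutpoints are the line evaluated at 40% and 60% HRR. Cohorts are
then stratified by MET capacity (VO2max/3.5: <10 / 10–13 / >13 MET) and
group cutpoints compared by one-way ANOVA with Welch–Bonferroni pairwise
contrasts; signed deviations from the absolute 1952/5725 thresholds and
cutpoint–covariate r² (VO2max, age, BMI) quantify what fitness explains.

A seeded synthetic-cohort generator (`relcal.simulate`) reproduces the
protocol's structure — fitness-dependent heart-rate response, demand-driven
counts, 85% HRmax termination — so the whole pipeline is testable without
any device data. See `docs/methods.md` for the generator's model and its
limits.

## Worked example

Simulate one high-fit subject, calibrate them, and classify their own test
epochs under both schemes:

```
$ relcal simulate --n-low 0 --n-moderate 0 --n-high 1 --seed 42 --out-dir demo
$ relcal calibrate --hr demo/hr_S001.csv --counts demo/counts_S001.csv \
      --profile demo/profile_S001.csv --out demo/cuts_S001.csv
Subject S001 (HRrest 54, HRmax 195, VO2max 52.3 ml·kg⁻¹·min⁻¹)
speed_kph  mean_hr  mean_counts  hrr_pct
      6.4     85.3       2570.5     22.4
      8.0    132.2       7230.2     55.7
      9.6    145.0       8810.6     64.7
...
slope           145.3254  (SE 5.9754)
intercept      -713.1606  (SE 304.5152)
R-squared:            0.9983
moderate cut (40% HRR): 5100 counts·min⁻¹
vigorous cut (60% HRR): 8006 counts·min⁻¹
```

The fitted line predicts 5100 counts·min⁻¹ at 40% HRR and 8006 at 60% HRR
(this simulated subject's true generating cutpoints are 5124 and 7961).
Classifying the same minutes under the two schemes:

```
$ relcal classify --counts demo/counts_S001.csv --cutpoints demo/cuts_S001.csv --out i.csv
counts_S001 [individualized]: light 15, moderate 5, vigorous 5 min
$ relcal classify --counts demo/counts_S001.csv --absolute --out a.csv
counts_S001 [freedson_absolute]: light 10, moderate 5, vigorous 10 min
```

The absolute scheme credits this fit subject with twice the vigorous time:
their individualized vigorous threshold (8006) sits far above the absolute
5725, so minutes that are vigorous "for anyone" are not vigorous *for them*.
`relcal cohort --table ... --out-dir ...` produces the corresponding
group-level tables (group means ± SD, ANOVA, deviations, correlations) for
a whole study.

The same machinery is available as a library, statsmodels-style:

```python
from relcal import CutpointCalibration, simulate_cohort, SimulationConfig

subject = simulate_cohort(SimulationConfig(n_low=0, n_moderate=0, n_high=1, seed=42))[0]
results = CutpointCalibration.from_session(subject.session).fit()
print(results.summary())
print(results.derive_cutpoints(40, 60))
```

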