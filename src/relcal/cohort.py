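"""Cohort-level analysis: fitness stratification, group comparisons,
deviations from absolute cutpoints, and cutpoint–covariate correlations.

Fitness groups follow the MET-capacity split <10 / 10–13 / >13 MET
(MET capacity = VO2max / 3.5; both boundary values fall in the moderate
group). Group means are compared with a one-way ANOVA; post-hoc contrasts
use pairwise Welch t-tests with Bonferroni adjustment, a deliberately
conservative and fully reproducible choice. Significance threshold 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import CutpointCalibration
from .exceptions import (
    ComparisonError,
    InvalidProfileError,
    UndefinedCorrelationError,
)
from .types import (
    GROUP_LABELS,
    GROUPS,
    CutpointPair,
    CutpointScheme,
    FitnessGroup,
    StageSummary,
    SubjectProfile,
)

ALPHA = 0.05

Covariate = Literal["vo2max", "age", "bmi"]
CohortRecord = tuple[SubjectProfile, CutpointPair]


def assign_fitness_group(vo2max: float) -> FitnessGroup:
    """Map a VO2max (ml·kg⁻¹·min⁻¹) to its fitness stratum via MET capacity."""
    if vo2max <= 0:
        raise InvalidProfileError("vo2max must be > 0")
    met = vo2max / 3.5
    if met < 10.0:
        return GROUPS[0]
    if met <= 13.0:
        return GROUPS[1]
    return GROUPS[2]


def group_cutpoint_stats(cohort: Sequence[CohortRecord]) -> pd.DataFrame:
    """Per-group n, mean and sample SD (ddof=1) of the moderate and vigorous
    cutpoints. Empty groups appear with n=0 and NaN statistics; singleton
    groups report a mean but no SD."""
    rows = []
    by_group: dict[str, list[CutpointPair]] = {g: [] for g in GROUP_LABELS}
    for profile, pair in cohort:
        by_group[assign_fitness_group(profile.vo2max).label].append(pair)
    for label in GROUP_LABELS:
        pairs = by_group[label]
        n = len(pairs)
        for intensity, attr in (("moderate", "moderate_cut"), ("vigorous", "vigorous_cut")):
            vals = np.array([getattr(p, attr) for p in pairs], dtype=float)
            rows.append(
                {
                    "group": label,
                    "intensity": intensity,
                    "n": n,
                    "mean": float(vals.mean()) if n else np.nan,
                    "sd": float(vals.std(ddof=1)) if n >= 2 else np.nan,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PairwiseContrast:
    group_a: str
    group_b: str
    mean_difference: float
    p_adjusted: float


@dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA across fitness groups plus Bonferroni-adjusted
    pairwise Welch contrasts. Groups with fewer than two members are
    excluded (listed in ``excluded``)."""

    groups: tuple[str, ...]
    n: tuple[int, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    f_statistic: float
    anova_p: float
    pairwise: tuple[PairwiseContrast, ...]
    excluded: tuple[str, ...] = ()

    @property
    def significant(self) -> bool:
        return self.anova_p < ALPHA

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.groups,
                "n": self.n,
                "mean": self.means,
                "sd": self.sds,
                "F": self.f_statistic,
                "anova_p": self.anova_p,
            }
        )


def compare_groups(values_by_group: Mapping[str, Sequence[float]]) -> GroupComparison:
    """Compare a cutpoint (or any per-subject quantity) across groups."""
    usable = {
        g: np.asarray(v, dtype=float)
        for g, v in values_by_group.items()
        if len(v) >= 2
    }
    excluded = tuple(g for g in values_by_group if g not in usable)
    if len(usable) < 2:
        raise ComparisonError(
            f"need >= 2 groups with >= 2 members; got {len(usable)}"
        )
    labels = tuple(usable)
    arrays = [usable[g] for g in labels]
    f_stat, p = stats.f_oneway(*arrays)
    n_pairs = len(labels) * (len(labels) - 1) // 2
    contrasts = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            t_res = stats.ttest_ind(arrays[i], arrays[j], equal_var=False)
            contrasts.append(
                PairwiseContrast(
                    labels[i],
                    labels[j],
                    float(arrays[i].mean() - arrays[j].mean()),
                    float(min(1.0, t_res.pvalue * n_pairs)),
                )
            )
    return GroupComparison(
        groups=labels,
        n=tuple(len(a) for a in arrays),
        means=tuple(float(a.mean()) for a in arrays),
        sds=tuple(float(a.std(ddof=1)) for a in arrays),
        f_statistic=float(f_stat),
        anova_p=float(p),
        pairwise=tuple(contrasts),
        excluded=excluded,
    )


def cutpoint_deviation(
    pair: CutpointPair, absolute: CutpointScheme
) -> tuple[float, float]:
    """Signed individualized-minus-absolute differences, counts·min⁻¹,
    at the moderate and vigorous intensities."""
    return (
        pair.moderate_cut - absolute.moderate_cut,
        pair.vigorous_cut - absolute.vigorous_cut,
    )


@dataclass(frozen=True)
class CovariateAssociation:
    """Squared Pearson correlation between a subject covariate and the
    individualized cutpoints at one intensity."""

    covariate: Covariate
    intensity_pct: float
    r_squared: float
    n: int


def _covariate_values(profiles: Iterable[SubjectProfile], covariate: Covariate) -> np.ndarray:
    if covariate == "bmi":
        return np.array([p.bmi for p in profiles], dtype=float)
    if covariate in ("vo2max", "age"):
        return np.array([getattr(p, covariate) for p in profiles], dtype=float)
    raise ValueError(f"unknown covariate {covariate!r}")


def correlate_cutpoints(
    cohort: Sequence[CohortRecord],
    covariate: Covariate,
    intensity: Literal["moderate", "vigorous"] = "moderate",
) -> CovariateAssociation:
    """How much cutpoint variability the covariate explains (r²)."""
    if len(cohort) < 3:
        raise ComparisonError("need >= 3 subjects for a correlation")
    profiles = [p for p, _ in cohort]
    x = _covariate_values(profiles, covariate)
    attr = "moderate_cut" if intensity == "moderate" else "vigorous_cut"
    y = np.array([getattr(pair, attr) for _, pair in cohort], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            f"zero variance in {covariate if np.ptp(x) == 0 else 'cutpoints'}"
        )
    r, _ = stats.pearsonr(x, y)
    pct = (
        cohort[0][1].moderate_pct if intensity == "moderate" else cohort[0][1].vigorous_pct
    )
    return CovariateAssociation(covariate, float(pct), float(r**2), len(cohort))


def group_regression_table(
    records: Sequence[tuple[SubjectProfile, Sequence[StageSummary]]]
) -> pd.DataFrame:
    """Pooled counts-vs-%HRR regression line per fitness group.

    Stage points from all subjects in a group are pooled and a single OLS
    line fitted, yielding a plottable per-group table (group, slope,
    intercept, r_squared, n_points)."""
    pooled: dict[str, list[StageSummary]] = {g: [] for g in GROUP_LABELS}
    for profile, summaries in records:
        pooled[assign_fitness_group(profile.vo2max).label].extend(summaries)
    rows = []
    for label in GROUP_LABELS:
        pts = pooled[label]
        if len(pts) >= 3:
            model = CutpointCalibration(pts, "counts_on_hrr").fit()
            rows.append(
                {
                    "group": label,
                    "slope": model.slope,
                    "intercept": model.intercept,
                    "r_squared": model.r_squared,
                    "n_points": model.n_points,
                }
            )
        else:
            rows.append(
                {
                    "group": label,
                    "slope": np.nan,
                    "intercept": np.nan,
                    "r_squared": np.nan,
                    "n_points": len(pts),
                }
            )
    return pd.DataFrame(rows)
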