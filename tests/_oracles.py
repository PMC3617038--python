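"""Independent brute-force oracles used only by the tests.

Each function recomputes a statistic from first principles (grid search,
explicit sums, per-item loops) without touching the library code paths it
checks, nor numpy/scipy/statsmodels fitting routines.
"""

from __future__ import annotations

import math

import numpy as np


def grid_search_ols(x, y, rounds: int = 9, grid: int = 41):
    """Least-squares line by iteratively-zoomed grid search over
    (slope, intercept); refines well below 0.01% of either parameter."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    # search in centred coordinates y ~ a + s*(x - mean(x)), where the level
    # and slope are decoupled and the zoomed grid cannot lose the optimum
    xc = x - float(np.mean(x))
    span_x = max(float(np.ptp(x)), 1e-9)
    s_c = 0.0
    a_c = float(np.mean(y))
    s_half = 4.0 * (float(np.ptp(y)) / span_x + 1.0)
    a_half = float(np.ptp(y)) + 1.0
    for _ in range(rounds):
        slopes = np.linspace(s_c - s_half, s_c + s_half, grid)
        levels = np.linspace(a_c - a_half, a_c + a_half, grid)
        pred = slopes[:, None, None] * xc[None, None, :] + levels[None, :, None]
        sse = np.sum((pred - y[None, None, :]) ** 2, axis=2)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        s_c, a_c = float(slopes[i]), float(levels[j])
        shrink = 4.0 / (grid - 1)
        s_half *= shrink
        a_half *= shrink
    return s_c, a_c - s_c * float(np.mean(x))


def anova_f(groups):
    """One-way ANOVA F from explicit between/within sums of squares."""
    all_values = [v for g in groups for v in g]
    grand = sum(all_values) / len(all_values)
    k = len(groups)
    n_total = len(all_values)
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum((v - sum(g) / len(g)) ** 2 for g in groups for v in g)
    return (ssb / (k - 1)) / (ssw / (n_total - k))


def sample_sd(values):
    """Two-pass sample standard deviation (n−1 denominator)."""
    n = len(values)
    mean = sum(values) / n
    return math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))


def pearson_r_squared(x, y):
    """Squared Pearson correlation from the covariance formula, by loop."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy * sxy / (sxx * syy)


def recount_minutes(counts_per_min, moderate_cut, vigorous_cut, minutes_per_epoch=1.0):
    """Per-epoch loop-and-count classification tally."""
    light = moderate = vigorous = 0
    for c in counts_per_min:
        if c >= vigorous_cut:
            vigorous += 1
        elif c >= moderate_cut:
            moderate += 1
        else:
            light += 1
    return (
        light * minutes_per_epoch,
        moderate * minutes_per_epoch,
        vigorous * minutes_per_epoch,
    )
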