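"""Summary statistics for assay read-outs.

Unpaired t-tests, one-way ANOVA, mean ± s.d./s.e.m. summaries and
1.5×IQR box-and-whisker summaries, with deterministic handling of the
degenerate inputs (zero-variance groups) that small imaging datasets
produce. Quartiles use the linear-interpolation convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "BoxSummary",
    "ttest_unpaired",
    "anova_oneway",
    "box_summary",
    "summarize",
    "p_to_stars",
]

#: the significance legend used throughout: *, **, ***, ****
DEFAULT_STAR_LEGEND = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.1, "*"))


@dataclass(frozen=True)
class BoxSummary:
    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def _clean(x, min_n, name="group"):
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < min_n:
        raise ValueError(f"{name} needs at least {min_n} observations")
    return arr


def ttest_unpaired(a, b, two_tailed: bool = True, equal_var: bool = True):
    """Unpaired Student's t-test (pooled variance by default; set
    ``equal_var=False`` for Welch).

    Returns ``(t, df, p)``. Two groups with zero pooled variance give
    t = 0, p = 1 when their means agree and raise otherwise (the
    statistic is undefined).
    """
    a = _clean(a, 2, "a")
    b = _clean(b, 2, "b")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            df = a.size + b.size - 2
            return 0.0, float(df), 1.0
        raise ValueError("zero variance with unequal means: t is degenerate")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    df = float(res.df)
    p = float(res.pvalue) if two_tailed else float(res.pvalue) / 2.0
    return float(res.statistic), df, p


def anova_oneway(*groups):
    """Classical one-way ANOVA.

    Returns ``(F, df_between, df_within, p)``. All observations
    identical gives F = 0, p = 1. For two groups F equals the square of
    the pooled t statistic.
    """
    gs = [_clean(g, 2, f"group {i}") for i, g in enumerate(groups)]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    df1 = len(gs) - 1
    df2 = sum(g.size for g in gs) - len(gs)
    allvals = np.concatenate(gs)
    if np.all(allvals == allvals[0]):
        return 0.0, float(df1), float(df2), 1.0
    res = sps.f_oneway(*gs)
    # the between-group sum of squares can underflow to a tiny negative
    # number when group means agree to machine precision; clamp so the
    # p-value stays defined
    f = max(float(res.statistic), 0.0)
    return f, float(df1), float(df2), float(sps.f.sf(f, df1, df2))


def box_summary(x) -> BoxSummary:
    """Box-and-whisker summary: quartiles by linear interpolation,
    whiskers at the extreme data points within 1.5×IQR of the
    quartiles, points beyond the fences listed as outliers."""
    arr = _clean(x, 1, "x")
    q1, med, q3 = (float(q) for q in np.quantile(arr, [0.25, 0.5, 0.75]))
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    outliers = tuple(float(v) for v in np.sort(arr[(arr < lo_fence) | (arr > hi_fence)]))
    return BoxSummary(
        q1=q1,
        median=med,
        q3=q3,
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=outliers,
    )


def summarize(x, mode: str = "sem"):
    """Mean with spread: ``mode='sd'`` gives the sample s.d. (n-1
    denominator), ``'sem'`` gives s.d./sqrt(n). Returns
    ``(mean, spread, n)``; a single observation yields spread None."""
    if mode not in ("sem", "sd"):
        raise ValueError(f"unknown mode {mode!r}")
    arr = _clean(x, 1, "x")
    mean = float(arr.mean())
    if arr.size < 2:
        return mean, None, 1
    sd = float(arr.std(ddof=1))
    spread = sd if mode == "sd" else sd / float(np.sqrt(arr.size))
    return mean, spread, int(arr.size)


def p_to_stars(p: float, legend=DEFAULT_STAR_LEGEND) -> str:
    """Map a p-value to a star annotation via a configurable legend
    (default thresholds 0.0001/0.001/0.01/0.1)."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    for cutoff, stars in sorted(legend):
        if p < cutoff:
            return stars
    return "ns"
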