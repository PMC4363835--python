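"""Descriptive layer: group summaries, effect sizes, trends, figure data.

Works from summary statistics (n, mean, SD) as well as raw vectors, so
printed cohort tables can be reproduced and checked without record-level
data: exact pooling of subgroup summaries, two-sample t-tests from
summaries, and Cohen's d with a noncentral-t confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "GroupSummary",
    "EffectSize",
    "DescriptivesError",
    "summarize",
    "cohens_d",
    "ttest_from_summary",
    "pool_groups",
    "age_trend",
    "qq_coordinates",
    "histogram_counts",
]


class DescriptivesError(ValueError):
    pass


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise DescriptivesError(f"group {self.label!r}: n must be >= 2")
        if self.sd < 0:
            raise DescriptivesError(f"group {self.label!r}: negative sd")


@dataclass(frozen=True)
class EffectSize:
    d: float
    ci_low: float
    ci_high: float
    method: str  # "unweighted_sd" or "pooled_sd"


def summarize(values: Sequence[float], label: str = "") -> GroupSummary:
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    return GroupSummary(label=label, n=len(x), mean=float(x.mean()), sd=float(x.std(ddof=1)))


def _d_ci_noncentral(d: float, n_a: int, n_b: int, level: float) -> tuple[float, float]:
    """CI for a standardized mean difference by noncentral-t inversion.

    The observed d maps to a t statistic t = d / sqrt(1/n_a + 1/n_b); the
    confidence bounds are the noncentrality parameters at which that t sits
    at the (1 - alpha/2) and alpha/2 quantiles, mapped back to the d scale.
    Asymmetric around d, as noncentral intervals are.
    """
    scale = np.sqrt(1.0 / n_a + 1.0 / n_b)
    df = n_a + n_b - 2
    t_obs = d / scale
    alpha = 1.0 - level

    def cdf(nc: float) -> float:
        v = stats.nct.cdf(t_obs, df, nc)
        if np.isnan(v):  # far tails can underflow; the limit is known
            return 0.0 if nc > t_obs else 1.0
        return float(v)

    def bound(target: float) -> float:
        # cdf is decreasing in nc; expand the bracket until it straddles target
        lo, hi, width = t_obs - 2.0, t_obs + 2.0, 2.0
        while cdf(lo) < target:
            width *= 2.0
            lo = t_obs - width
        while cdf(hi) > target:
            width *= 2.0
            hi = t_obs + width
        return optimize.brentq(lambda nc: cdf(nc) - target, lo, hi, xtol=1e-10)

    nc_low = bound(1.0 - alpha / 2.0)
    nc_high = bound(alpha / 2.0)
    return nc_low * scale, nc_high * scale


def cohens_d(
    a: GroupSummary,
    b: GroupSummary,
    method: str = "unweighted_sd",
    ci_method: str = "noncentral_t",
    level: float = 0.95,
) -> EffectSize:
    """Cohen's d between two summarized groups, with a confidence interval.

    ``unweighted_sd`` (default) standardizes by sqrt((sd_a^2 + sd_b^2)/2),
    the plain average of the two variances; ``pooled_sd`` uses the
    sample-size-weighted pooled SD. The CI is by noncentral-t inversion
    (asymmetric) or, with ``ci_method='normal'``, the symmetric large-sample
    approximation.
    """
    if a.sd <= 0 or b.sd <= 0:
        raise DescriptivesError("Cohen's d needs strictly positive SDs")
    diff = a.mean - b.mean
    if method == "unweighted_sd":
        denom = np.sqrt((a.sd**2 + b.sd**2) / 2.0)
    elif method == "pooled_sd":
        denom = np.sqrt(
            ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
        )
    else:
        raise DescriptivesError(f"unknown d method {method!r}")
    d = diff / denom
    if ci_method == "noncentral_t":
        lo, hi = _d_ci_noncentral(d, a.n, b.n, level)
    elif ci_method == "normal":
        # large-sample variance of d (Hedges & Olkin form)
        var_d = (a.n + b.n) / (a.n * b.n) + d**2 / (2.0 * (a.n + b.n))
        z = stats.norm.ppf(0.5 + level / 2.0)
        lo, hi = d - z * np.sqrt(var_d), d + z * np.sqrt(var_d)
    else:
        raise DescriptivesError(f"unknown ci method {ci_method!r}")
    return EffectSize(d=float(d), ci_low=float(lo), ci_high=float(hi), method=method)


def ttest_from_summary(
    a: GroupSummary, b: GroupSummary, variant: str = "pooled"
) -> tuple[float, float, float]:
    """Two-sided unpaired t-test from group summaries: (t, df, p)."""
    if variant not in ("pooled", "welch"):
        raise DescriptivesError(f"unknown t-test variant {variant!r}")
    res = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df = float(a.n + b.n - 2)
    else:  # Welch-Satterthwaite
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def pool_groups(groups: Sequence[GroupSummary], label: str = "total") -> GroupSummary:
    """Exact pooled summary of disjoint groups.

    mean = sum(n_i m_i) / sum(n_i); variance combines within-group sums of
    squares and between-group mean dispersion:
    [(sum (n_i - 1) s_i^2) + (sum n_i (m_i - m)^2)] / (sum n_i - 1).
    """
    if not groups:
        raise DescriptivesError("no groups to pool")
    if len(groups) == 1:
        g = groups[0]
        return GroupSummary(label=label, n=g.n, mean=g.mean, sd=g.sd)
    n_tot = sum(g.n for g in groups)
    mean = sum(g.n * g.mean for g in groups) / n_tot
    ss = sum((g.n - 1) * g.sd**2 for g in groups)
    ss += sum(g.n * (g.mean - mean) ** 2 for g in groups)
    sd = float(np.sqrt(ss / (n_tot - 1)))
    return GroupSummary(label=label, n=n_tot, mean=float(mean), sd=sd)


def age_trend(records: pd.DataFrame) -> tuple[float, float, float]:
    """OLS line of score on age: (slope per year, intercept, two-sided p).

    Also the source of the age-scatter figure data (the raw (age, score)
    pairs are the coordinates).
    """
    age = np.asarray(records["age"], dtype=float)
    score = np.asarray(records["meq_total"], dtype=float)
    ok = np.isfinite(age) & np.isfinite(score)
    age, score = age[ok], score[ok]
    if len(np.unique(age)) < 2:
        raise DescriptivesError("age is constant; no trend estimable")
    res = stats.linregress(age, score)
    # two points interpolate exactly; the slope p-value needs n >= 3
    p = float(res.pvalue) if len(age) >= 3 else float("nan")
    return float(res.slope), float(res.intercept), p


def qq_coordinates(values: Sequence[float]) -> pd.DataFrame:
    """Normal Q-Q coordinates: ordered values vs N(0,1) quantiles.

    Plotting positions (i - 0.5)/n. A ceiling-censored sample shows its
    compressed upper tail as points falling below the line through the bulk.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n < 3:
        raise DescriptivesError("need at least 3 values")
    pp = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame(
        {"theoretical_quantile": stats.norm.ppf(pp), "ordered_value": x}
    )


def histogram_counts(
    values: Sequence[int],
    by: Sequence | None = None,
    lo: int = 16,
    hi: int = 86,
) -> pd.DataFrame:
    """Exact per-score counts, optionally split by group: (score, group, count).

    Scores must be integers within the scale range; the figure-data table the
    score-distribution histogram is drawn from.
    """
    vals = np.asarray(values)
    if not np.all(np.isfinite(np.asarray(vals, dtype=float))):
        raise DescriptivesError("scores contain missing values")
    ivals = np.asarray(np.round(np.asarray(vals, dtype=float)), dtype=int)
    if np.any(np.abs(np.asarray(vals, dtype=float) - ivals) > 1e-9):
        raise DescriptivesError("scores must be integers")
    if ivals.min() < lo or ivals.max() > hi:
        raise DescriptivesError(
            f"score outside [{lo}, {hi}]: {ivals.min()}..{ivals.max()}"
        )
    groups = np.asarray(by) if by is not None else np.array(["all"] * len(ivals))
    if len(groups) != len(ivals):
        raise DescriptivesError("group labels and values differ in length")
    df = pd.DataFrame({"score": ivals, "group": groups})
    counts = (
        df.groupby(["score", "group"], sort=True).size().reset_index(name="count")
    )
    return counts
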