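"""Group statistics: one-way ANOVA with Bonferroni post-hoc pairwise
t-tests, Cohen's d effect sizes, sample-size/power analysis and linear
age trends.

Group differences (degenerative / traumatic / control) are tested with a
classical one-way ANOVA at alpha = 0.05 followed, when significant, by
pairwise pooled-variance t-tests with Bonferroni correction. The power
analysis reports the per-group sample size needed to detect a pairwise
effect at 80% power and 5% significance. Age dependence is summarised by
an ordinary-least-squares trendline and its r-squared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class PowerSpec:
    """Two-sample power-analysis specification (Cohen's d scale)."""

    effect_size: float
    alpha: float = 0.05
    power: float = 0.80
    method: str = "normal_approx"  # or 'noncentral_t'

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")


@dataclass
class TrendResult:
    slope: float
    intercept: float
    r_squared: float


def one_way_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classical between/within F statistic and p-value.

    Degenerate input (zero variance everywhere with equal means) follows
    the convention F = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 observations")
    grand = np.concatenate(groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ss_between = sum(len(g) * (g.mean() - grand.mean()) ** 2 for g in groups)
    df_between = len(groups) - 1
    df_within = len(grand) - len(groups)
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, 1.0
        return math.inf, 0.0
    f_stat = (ss_between / df_between) / (ss_within / df_within)
    p = float(sps.f.sf(f_stat, df_between, df_within))
    return float(f_stat), p


def bonferroni_pairwise(
    groups: dict[str, np.ndarray] | list[np.ndarray]
) -> dict[tuple[str, str], float]:
    """Pairwise pooled-variance t-tests with Bonferroni-adjusted p-values.

    Adjusted p = raw p times the number of pairs, capped at 1.
    """
    if isinstance(groups, dict):
        named = list(groups.items())
    else:
        named = [(str(i), g) for i, g in enumerate(groups)]
    if len(named) < 2:
        raise ValueError("need at least 2 groups")
    n_pairs = len(named) * (len(named) - 1) // 2
    out: dict[tuple[str, str], float] = {}
    for i, (name_a, a) in enumerate(named):
        for name_b, b in named[i + 1 :]:
            a = np.asarray(a, dtype=float)
            b = np.asarray(b, dtype=float)
            if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
                raw = 1.0 if a.mean() == b.mean() else 0.0
            else:
                raw = float(sps.ttest_ind(a, b, equal_var=True).pvalue)
            out[(name_a, name_b)] = min(raw * n_pairs, 1.0)
    return out


def cohens_d(
    sample1=None, sample2=None, *, summaries: tuple[tuple[float, float, int],
                                                    tuple[float, float, int]] | None = None
) -> float:
    """Cohen's d: |mean difference| / pooled SD with (n-1)-weighted pooling.

    Either two samples or ``summaries=((mean, sd, n), (mean, sd, n))``.
    """
    if summaries is not None:
        (m1, s1, n1), (m2, s2, n2) = summaries
    else:
        a = np.asarray(sample1, dtype=float)
        b = np.asarray(sample2, dtype=float)
        m1, s1, n1 = a.mean(), a.std(ddof=1), len(a)
        m2, s2, n2 = b.mean(), b.std(ddof=1), len(b)
    if s1 == 0 and s2 == 0:
        raise ValueError("both SDs are zero; effect size undefined")
    pooled = math.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    return abs(m1 - m2) / pooled


def sample_size_for_power(spec: PowerSpec) -> int:
    """Smallest per-group n achieving the specified two-sample power.

    ``normal_approx``: n = 2 (z_{1-alpha/2} + z_power)^2 / d^2, ceiled.
    ``noncentral_t``: exact two-sided t-test power via the noncentral t
    distribution, searched upward from n = 2 (never smaller than the
    normal approximation).
    """
    if spec.effect_size <= 0:
        raise ValueError("effect size must be positive")
    z_alpha = sps.norm.ppf(1 - spec.alpha / 2)
    z_power = sps.norm.ppf(spec.power)
    n_normal = max(int(math.ceil(2 * ((z_alpha + z_power) / spec.effect_size) ** 2)), 1)
    if spec.method == "normal_approx":
        return n_normal
    if spec.method != "noncentral_t":
        raise ValueError(f"unknown method {spec.method!r}")
    n = max(n_normal, 2)
    while True:
        df = 2 * n - 2
        nc = spec.effect_size * math.sqrt(n / 2)
        t_crit = sps.t.ppf(1 - spec.alpha / 2, df)
        power = sps.nct.sf(t_crit, df, nc) + sps.nct.cdf(-t_crit, df, nc)
        if power >= spec.power:
            return n
        n += 1


def linear_trend(x, y) -> TrendResult:
    """OLS trendline of a metric against age with r^2 = 1 - SSres/SStot."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("trend needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("cannot fit a trend to constant x")
    res = sps.linregress(x, y)
    return TrendResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )
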