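"""Group statistics: one-way ANOVA, LSD post-hoc, FDR, and Pearson correlation.

Classical equal-variance (pooled) forms throughout: one-way ANOVA computed
either from raw observations or from group sufficient statistics (means, SDs,
sizes — these fully determine the F test, so summary-based recomputation is
exact), Fisher's Least Significant Difference post-hoc t tests on the pooled
within-group mean square, Benjamini-Hochberg step-up false-discovery-rate
control, and two-tailed Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    group_means: tuple[float, ...]
    group_sds: tuple[float, ...]
    group_ns: tuple[int, ...]
    ms_within: float


@dataclass
class PosthocResult:
    """Pairwise LSD comparisons keyed by (group index a, group index b), a < b."""

    t: dict[tuple[int, int], float]
    p: dict[tuple[int, int], float]
    df_within: int


@dataclass
class FdrResult:
    p: np.ndarray
    q: np.ndarray
    significant: np.ndarray
    alpha: float
    m: int = field(init=False)

    def __post_init__(self) -> None:
        self.m = len(self.p)


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


def anova_from_summary(
    means: Sequence[float], sds: Sequence[float], ns: Sequence[int]
) -> AnovaResult:
    """One-way ANOVA from group means, standard deviations and sizes.

    SS_between = sum n_g (m_g - grand mean)^2, SS_within = sum (n_g - 1) sd_g^2,
    F = MS_between / MS_within on (k - 1, N - k) degrees of freedom. These are
    the sufficient statistics of the one-way model, so the result is identical
    to the raw-data ANOVA.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=int)
    if not (means.shape == sds.shape == ns.shape) or means.ndim != 1:
        raise ValueError("means, sds and ns must be 1-D and equal length")
    k = means.size
    if k < 2:
        raise ValueError("ANOVA requires at least 2 groups")
    if np.any(ns < 2):
        raise ValueError("every group needs n >= 2")
    if np.any(sds < 0):
        raise ValueError("standard deviations must be nonnegative")
    N = int(ns.sum())
    grand = float((ns * means).sum() / N)
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * sds**2).sum())
    df_between, df_within = k - 1, N - k
    ms_within = ss_within / df_within
    if ms_within == 0:
        # round-off can leave ss_between ~ 1e-30 on exactly constant data
        if ss_between <= 1e-10 * N * max(1.0, grand**2):
            raise ValueError("F undefined: zero between- and within-group variance")
        f_stat, p = np.inf, 0.0
    else:
        f_stat = (ss_between / df_between) / ms_within
        p = float(sps.f.sf(f_stat, df_between, df_within))
    return AnovaResult(
        F=float(f_stat),
        df_between=df_between,
        df_within=df_within,
        p=p,
        group_means=tuple(means),
        group_sds=tuple(sds),
        group_ns=tuple(int(n) for n in ns),
        ms_within=ms_within,
    )


def anova_oneway(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way ANOVA on raw observations via the between/within decomposition."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("ANOVA requires at least 2 groups")
    for g in arrays:
        if g.ndim != 1 or g.size < 2:
            raise ValueError("every group needs n >= 2 observations")
        if not np.all(np.isfinite(g)):
            raise ValueError("observations must be finite")
    means = [float(g.mean()) for g in arrays]
    sds = [float(g.std(ddof=1)) for g in arrays]
    ns = [g.size for g in arrays]
    return anova_from_summary(means, sds, ns)


def ttest_two_sample(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int
) -> tuple[float, int, float]:
    """Pooled-variance two-sample t test from summary statistics.

    Returns (t, df, two-tailed p) with df = n1 + n2 - 2.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = np.sqrt(pooled_var * (1 / n1 + 1 / n2))
    if se == 0:
        if m1 == m2:
            raise ValueError("t undefined: zero pooled variance and equal means")
        return (np.inf if m1 > m2 else -np.inf), df, 0.0
    t = (m1 - m2) / se
    p = float(2 * sps.t.sf(abs(t), df))
    return float(t), df, p


def lsd_posthoc(groups: Sequence[Sequence[float]]) -> PosthocResult:
    """Fisher's LSD: pairwise t tests on the ANOVA pooled within-group variance.

    t_ab = (m_a - m_b) / sqrt(MS_within (1/n_a + 1/n_b)) with the full ANOVA
    within degrees of freedom; no multiplicity adjustment (which is what
    "least significant difference" means).
    """
    anova = anova_oneway(groups)
    arrays = [np.asarray(g, dtype=float) for g in groups]
    t_map: dict[tuple[int, int], float] = {}
    p_map: dict[tuple[int, int], float] = {}
    for a in range(len(arrays)):
        for b in range(a + 1, len(arrays)):
            ma, mb = arrays[a].mean(), arrays[b].mean()
            na, nb = arrays[a].size, arrays[b].size
            if anova.ms_within == 0:
                t = np.inf if ma != mb else 0.0
            else:
                t = (ma - mb) / np.sqrt(anova.ms_within * (1 / na + 1 / nb))
            t_map[(a, b)] = float(t)
            p_map[(a, b)] = float(2 * sps.t.sf(abs(t), anova.df_within))
    return PosthocResult(t=t_map, p=p_map, df_within=anova.df_within)


def bh_fdr(pvals: Sequence[float], alpha: float = 0.05) -> FdrResult:
    """Benjamini-Hochberg step-up FDR control.

    Significance: find the largest i with p_(i) <= (i/m) alpha and flag all
    hypotheses with p up to p_(i). Adjusted values q_(i) = min_{j >= i}
    m p_(j) / j, capped at 1, so that flagging q <= alpha is equivalent.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p-values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_sorted = np.minimum.accumulate((m * ranked / np.arange(1, m + 1))[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    passing = np.flatnonzero(ranked <= np.arange(1, m + 1) / m * alpha)
    significant = np.zeros(m, dtype=bool)
    if passing.size:
        cutoff = ranked[passing[-1]]
        significant = p <= cutoff
    return FdrResult(p=p.copy(), q=q, significant=significant, alpha=alpha)


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Sample Pearson r with two-tailed p via t = r sqrt((n-2)/(1-r^2))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    if x.size < 3:
        raise ValueError("correlation requires n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("values must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=x.size)
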