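"""Paired and two-group test kernels plus multiple-testing adjustment.

These are the building blocks of the differential enhancer and expression
calls: a classical paired t (closed form, vectorisable across regions), a
Wilcoxon signed-rank with exact mid-ranked enumeration for small n, a
Mann-Whitney rank-sum, Benjamini-Hochberg and Bonferroni adjustment, and a
Pearson correlation with its t-transform p-value.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "paired_t",
    "paired_t_rows",
    "wilcoxon_signed_rank",
    "wilcoxon_rank_sum",
    "bh_adjust",
    "bonferroni_adjust",
    "pearson_with_p",
]

INF_T = math.inf  # sentinel for a zero-variance, nonzero-mean difference


def paired_t(values_a, values_b) -> tuple[float, float]:
    """Classical paired t-test on per-pair differences, two-sided.

    Degenerate rules: all differences zero -> ``(0, 1)``; zero spread with a
    nonzero mean -> ``(±inf, 0)``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-D and equal length")
    if len(a) < 2:
        raise ValueError("paired t requires n >= 2")
    t, p = paired_t_rows((a - b)[None, :])
    return float(t[0]), float(p[0])


def paired_t_rows(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise paired t on a (regions x pairs) difference matrix.

    Returns (t, p) arrays; degenerate rows follow the scalar rules.
    """
    d = np.asarray(diffs, dtype=float)
    n = d.shape[1]
    if n < 2:
        raise ValueError("paired t requires n >= 2")
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    t = np.zeros(len(d))
    p = np.ones(len(d))
    ok = sd > 0
    t[ok] = mean[ok] / (sd[ok] / math.sqrt(n))
    p[ok] = 2.0 * sps.t.sf(np.abs(t[ok]), df=n - 1)
    degenerate = (~ok) & (mean != 0)
    t[degenerate] = np.sign(mean[degenerate]) * INF_T
    p[degenerate] = 0.0
    return t, p


def _signed_rank_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for the signed-rank sum with mid-ranks.

    Enumerates the 2^n equiprobable sign assignments by dynamic programming
    over doubled ranks (mid-ranks are half-integers, so doubling makes the
    achievable sums integral).
    """
    doubled = np.rint(2 * ranks).astype(np.int64)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: len(counts) - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2 * w_plus))
    cdf = counts[: w2 + 1].sum()
    sf = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(cdf, sf)))


def wilcoxon_signed_rank(
    values_a, values_b, exact_max_n: int = 25
) -> tuple[float, float]:
    """Wilcoxon signed-rank test, two-sided, paired order.

    Zero differences are dropped; ties in |difference| receive mid-ranks.
    The p-value is exact (sign enumeration) for up to ``exact_max_n``
    remaining pairs and a normal approximation with tie and continuity
    corrections above that.  Statistic reported is W+ (sum of positive ranks).
    All-zero differences return ``(0, 1)``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-D and equal length")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        return w_plus, _signed_rank_exact_p(ranks, w_plus)
    mu = n * (n + 1) / 4.0
    # tie correction: sum over tied groups of (t^3 - t) / 48
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
    if var <= 0:
        return w_plus, 1.0
    z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / math.sqrt(var)
    return w_plus, float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def wilcoxon_rank_sum(values_in, values_out) -> tuple[float, float]:
    """Mann-Whitney U test (two-sided) between two independent groups.

    Exact null distribution for small tie-free groups (both n <= 12), normal
    approximation with tie correction and continuity correction otherwise.
    Returns (U of the first group, p).
    """
    x = np.asarray(values_in, dtype=float)
    y = np.asarray(values_out, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(x), len(y)) <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size and (np.any(p < 0) | np.any(p > 1) | np.any(np.isnan(p))):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def bonferroni_adjust(pvals) -> np.ndarray:
    """Bonferroni-adjusted p-values (capped at 1), in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size and (np.any(p < 0) | np.any(p > 1) | np.any(np.isnan(p))):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(p * p.size, 1.0)


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson r and its two-sided p (t transform, df = n - 2).

    A zero-variance vector makes r undefined: returns ``(nan, nan)`` rather
    than raising, so callers can flag the pair as failed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be 1-D and equal length")
    if len(x) < 3:
        raise ValueError("correlation requires n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        return math.nan, math.nan
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
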