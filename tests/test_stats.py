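"""Statistical kernels against closed forms, exact enumeration and scipy."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from oncoenh.stats import (
    bh_adjust,
    bonferroni_adjust,
    paired_t,
    paired_t_rows,
    pearson_with_p,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)


# ---------------------------------------------------------------------------
# paired t
# ---------------------------------------------------------------------------


class TestPairedT:
    def test_closed_form_worked_case(self):
        # diffs [1.0, 1.2, 1.8]: t = mean / (sd/sqrt(3)), df = 2
        t, p = paired_t([1.0, 1.2, 1.8], [0.0, 0.0, 0.0])
        d = np.array([1.0, 1.2, 1.8])
        t_expected = d.mean() / (d.std(ddof=1) / math.sqrt(3))
        assert t == pytest.approx(t_expected, abs=1e-12)
        assert t == pytest.approx(5.547, abs=1e-3)
        assert p == pytest.approx(2 * sps.t.sf(t_expected, df=2), abs=1e-12)
        assert p == pytest.approx(0.031, abs=1e-3)

    def test_identical_vectors_degenerate(self):
        assert paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 1.0)

    def test_constant_nonzero_difference_sentinel(self):
        t, p = paired_t([2.0, 2.0, 2.0], [1.0, 1.0, 1.0])
        assert math.isinf(t) and t > 0 and p == 0.0

    def test_matches_scipy_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for n in (2, 3, 5, 10, 30):
            a, b = rng.normal(size=n), rng.normal(size=n)
            t, p = paired_t(a, b)
            ref = sps.ttest_rel(a, b)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=8), rng.normal(size=8)
        t1, p1 = paired_t(a, b)
        t2, p2 = paired_t(b, a)
        assert t1 == pytest.approx(-t2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_rows_match_scalar(self):
        rng = np.random.default_rng(2)
        d = rng.normal(size=(20, 6))
        t, p = paired_t_rows(d)
        for i in range(20):
            ti, pi = paired_t(d[i], np.zeros(6))
            assert t[i] == pytest.approx(ti, abs=1e-12)
            assert p[i] == pytest.approx(pi, abs=1e-12)

    def test_rejects_single_pair(self):
        with pytest.raises(ValueError):
            paired_t([1.0], [0.0])


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------


def signed_rank_enumeration_p(diffs):
    """Independent oracle: enumerate all 2^n sign assignments with mid-ranks."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    sums = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    sums = np.asarray(sums)
    cdf = np.mean(sums <= w_obs + 1e-9)
    sf = np.mean(sums >= w_obs - 1e-9)
    return min(1.0, 2 * min(cdf, sf))


class TestWilcoxonSignedRank:
    def test_all_positive_n5_exact(self):
        # all 5 diffs positive: only 2 of 32 assignments reach W >= 15
        w, p = wilcoxon_signed_rank([1, 2, 3, 4, 5], [0, 0, 0, 0, 0])
        assert w == 15.0
        assert p == pytest.approx(0.0625, abs=1e-12)

    def test_antisymmetric_pair(self):
        _, p = wilcoxon_signed_rank([0.0, 1.0], [1.0, 0.0])
        assert p == 1.0

    def test_all_zero_differences(self):
        assert wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0]) == (0.0, 1.0)

    def test_exact_matches_enumeration_with_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n = int(rng.integers(3, 11))
            # integer differences force ties in |d|
            d = rng.integers(-3, 4, size=n).astype(float)
            if np.all(d == 0):
                continue
            _, p = wilcoxon_signed_rank(d, np.zeros(n))
            assert p == pytest.approx(signed_rank_enumeration_p(d), abs=1e-12)

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = int(rng.integers(4, 15))
            d = rng.normal(size=n)  # continuous: no ties, no zeros
            _, p = wilcoxon_signed_rank(d, np.zeros(n))
            ref = sps.wilcoxon(d, mode="exact")
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approximation_close_to_exact(self):
        # same data scored by both branches: approx within a few 1e-3 of exact
        rng = np.random.default_rng(8)
        for _ in range(10):
            d = rng.normal(size=20)
            _, p_exact = wilcoxon_signed_rank(d, np.zeros(20), exact_max_n=25)
            _, p_approx = wilcoxon_signed_rank(d, np.zeros(20), exact_max_n=5)
            assert p_approx == pytest.approx(p_exact, abs=2e-2)


# ---------------------------------------------------------------------------
# rank-sum
# ---------------------------------------------------------------------------


def rank_sum_enumeration_p(x, y):
    """Enumerate all C(n1+n2, n1) group labelings of the pooled sample."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    n = len(pooled)
    us = []
    for combo in itertools.combinations(range(n), n1):
        r = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
        us.append(r)
    us = np.asarray(us)
    mu = len(x) * len(y) / 2
    dev = abs(u_obs - mu)
    return float(np.mean(np.abs(us - mu) >= dev - 1e-9))


class TestRankSum:
    def test_worked_case_exact(self):
        u, p = wilcoxon_rank_sum([5, 6, 7], [1, 2, 3])
        assert u == 9.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_values(self):
        _, p = wilcoxon_rank_sum([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert p == 1.0

    def test_matches_enumeration_small_n(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n1, n2 = int(rng.integers(2, 8)), int(rng.integers(2, 8))
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            _, p = wilcoxon_rank_sum(x, y)
            assert p == pytest.approx(rank_sum_enumeration_p(x, y), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------


def bh_direct(p):
    """Direct step-up formula oracle."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = p[order] * m / np.arange(1, m + 1)
    for i in range(m - 2, -1, -1):
        q[i] = min(q[i], q[i + 1])
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


class TestBH:
    def test_hand_worked_case(self):
        got = bh_adjust([0.001, 0.01, 0.02, 0.8])
        assert np.allclose(got, [0.004, 0.02, 0.02 * 4 / 3, 0.8])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_equal(self):
        assert np.allclose(bh_adjust([0.03] * 10), 0.03)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=1000))
    def test_matches_step_up_formula(self, pvals):
        got = bh_adjust(pvals)
        assert np.allclose(got, bh_direct(pvals), atol=1e-12)
        assert np.all(got >= np.asarray(pvals) - 1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(size=200)
        perm = rng.permutation(200)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_bonferroni(self):
        assert np.allclose(bonferroni_adjust([0.01, 0.4]), [0.02, 0.8])
        assert bonferroni_adjust([0.9, 0.9])[0] == 1.0


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------


class TestPearson:
    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(size=10), rng.normal(size=10)
        r, p = pearson_with_p(x, y)
        r_direct = np.cov(x, y)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert r == pytest.approx(r_direct, abs=1e-12)
        t = r_direct * math.sqrt(8 / (1 - r_direct**2))
        assert p == pytest.approx(2 * sps.t.sf(abs(t), df=8), abs=1e-12)

    def test_perfect_and_anti_correlation(self):
        x = np.arange(5.0)
        assert pearson_with_p(x, x)[0] == pytest.approx(1.0)
        assert pearson_with_p(x, -x)[0] == pytest.approx(-1.0)

    def test_zero_variance_flags_undefined(self):
        r, p = pearson_with_p(np.ones(5), np.arange(5.0))
        assert math.isnan(r) and math.isnan(p)
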