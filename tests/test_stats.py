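"""Oracle and property tests for the statistical primitives.

Every operation is checked against an independent brute-force oracle:
exhaustive enumeration of rank assignments for the rank-sum test, the
closed-form chi-square survival series for Fisher combination, exact
fraction enumeration for the hypergeometric tail, hand-executed step-up for
BH, and hand-computed product-limit / observed-minus-expected arithmetic
for the survival primitives.
"""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crgi.stats import (
    Alternative,
    bh_adjust,
    chi_square_2x2,
    fisher_combine,
    hypergeom_tail,
    km_curve,
    logrank_test,
    pearson,
    rank_sum_test,
    two_sample_t,
)


# ---------------------------------------------------------------------------
# independent oracles

def exact_ranksum_p(x, y, alternative: Alternative) -> float:
    """Enumerate all C(n+m, n) assignments of pooled ranks to the x group."""
    pooled = sorted(x) + sorted(y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free input"
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    m = len(x)
    u_obs = sum(ranks[v] for v in x) - m * (m + 1) / 2
    n_total = len(pooled)
    all_ranks = range(1, n_total + 1)
    count_le = count_ge = total = 0
    for combo in itertools.combinations(all_ranks, m):
        u = sum(combo) - m * (m + 1) / 2
        total += 1
        count_le += u <= u_obs
        count_ge += u >= u_obs
    if alternative is Alternative.LESS:
        return count_le / total
    if alternative is Alternative.GREATER:
        return count_ge / total
    return min(1.0, 2 * min(count_le, count_ge) / total)


def chi2_sf_closed_form(x: float, df: int) -> float:
    """Survival function of chi-square with even df: exp(-x/2)·Σ (x/2)^j/j!."""
    assert df % 2 == 0
    k = df // 2
    half = x / 2.0
    term, acc = 1.0, 1.0
    for j in range(1, k):
        term *= half / j
        acc += term
    return math.exp(-half) * acc


def hypergeom_tail_exact(k, K, n, N) -> Fraction:
    total = Fraction(0)
    for i in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, i) * math.comb(N - K, n - i), math.comb(N, n))
    return total


def bh_stepup_oracle(ps):
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, ps[i] * m / rank)
        adj[i] = running
    return adj


# ---------------------------------------------------------------------------
# rank-sum test

class TestRankSum:
    def test_small_sample_exact_examples(self):
        assert rank_sum_test([1, 2, 3], [4, 5, 6], Alternative.LESS).p_value == pytest.approx(0.05)
        assert rank_sum_test([4, 5, 6], [1, 2, 3], Alternative.LESS).p_value == pytest.approx(1.0)
        assert rank_sum_test([1, 2], [3, 4], Alternative.LESS).p_value == pytest.approx(1 / 6)

    def test_matches_enumeration_oracle_on_random_instances(self):
        """Exact path equals exhaustive rank-assignment enumeration."""
        rng = np.random.default_rng(42)
        for _ in range(60):
            n = int(rng.integers(1, 7))
            m = int(rng.integers(1, 13 - n))
            vals = rng.permutation(40)[: n + m].astype(float)
            x, y = vals[:n], vals[n:]
            for alt in (Alternative.LESS, Alternative.GREATER):
                got = rank_sum_test(x, y, alt).p_value
                want = exact_ranksum_p(list(x), list(y), alt)
                assert got == pytest.approx(want, abs=1e-12)

    def test_degenerate_all_identical(self):
        res = rank_sum_test([1.0, 1.0], [1.0, 1.0, 1.0], Alternative.LESS)
        assert res.p_value == 1.0 and res.degenerate

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0], Alternative.LESS)

    def test_directional_complementarity(self):
        """Under one distribution, both directions cannot be simultaneously small."""
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=20), rng.normal(size=25)
        pl = rank_sum_test(x, y, Alternative.LESS).p_value
        pg = rank_sum_test(x, y, Alternative.GREATER).p_value
        assert pl + pg >= 1.0  # continuity correction makes the sum exceed 1

    def test_null_calibration(self):
        """One-sided rejection rate at 0.05 sits in the exact binomial 99% CI."""
        from scipy.stats import binom

        rng = np.random.default_rng(2024)
        n_sim, alpha = 2000, 0.05
        rejections = 0
        for _ in range(n_sim):
            x = rng.normal(size=15)
            y = rng.normal(size=15)
            rejections += rank_sum_test(x, y, Alternative.LESS).p_value < alpha
        lo = binom.ppf(0.005, n_sim, alpha)
        hi = binom.ppf(0.995, n_sim, alpha)
        assert lo <= rejections <= hi


# ---------------------------------------------------------------------------
# Fisher combination

class TestFisherCombine:
    def test_identities(self):
        assert fisher_combine([1.0, 1.0]) == pytest.approx(1.0)
        assert fisher_combine([0.2]) == 0.2

    def test_against_closed_form(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            k = int(rng.integers(2, 8))
            ps = rng.uniform(1e-6, 1.0, size=k)
            stat = -2.0 * np.sum(np.log(ps))
            want = chi2_sf_closed_form(stat, 2 * k)
            assert fisher_combine(ps) == pytest.approx(want, abs=1e-12)

    def test_known_value(self):
        # -2(ln .05 + ln .05) = 11.9829...; chi-square df 4 upper tail
        want = chi2_sf_closed_form(-2 * (math.log(0.05) * 2), 4)
        assert fisher_combine([0.05, 0.05]) == pytest.approx(want, rel=1e-12)

    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6), st.integers(0, 5))
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_each_input(self, ps, idx):
        """Decreasing any input p never increases the combined p."""
        idx = idx % len(ps)
        smaller = list(ps)
        smaller[idx] = smaller[idx] / 2
        assert fisher_combine(smaller) <= fisher_combine(ps) + 1e-15

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fisher_combine([0.0, 0.5])
        with pytest.raises(ValueError):
            fisher_combine([1.5])


# ---------------------------------------------------------------------------
# BH adjustment

class TestBH:
    @pytest.mark.parametrize(
        "ps, want",
        [
            ([0.05], [0.05]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([1.0, 1.0], [1.0, 1.0]),
        ],
    )
    def test_examples(self, ps, want):
        assert bh_adjust(ps) == pytest.approx(want)

    def test_matches_stepup_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            ps = rng.uniform(1e-4, 1.0, size=int(rng.integers(1, 40))).tolist()
            assert bh_adjust(ps) == pytest.approx(bh_stepup_oracle(ps))

    def test_selection_consistency_with_classical_rule(self):
        """Thresholding adjusted values selects the classical step-up set."""
        rng = np.random.default_rng(10)
        for q in (0.05, 0.1, 0.25):
            ps = np.concatenate([rng.uniform(0, 0.01, 5), rng.uniform(0, 1, 45)])
            adj = bh_adjust(ps)
            selected = set(np.flatnonzero(adj <= q))
            # classical: largest k with p_(k) <= k q / m, select the k smallest
            order = np.argsort(ps)
            m = len(ps)
            k_star = 0
            for rank, i in enumerate(order, start=1):
                if ps[i] <= rank * q / m:
                    k_star = rank
            classical = set(order[:k_star])
            assert selected == classical

    def test_adjusted_at_least_raw_and_empty(self):
        ps = [0.2, 0.01, 0.7]
        assert np.all(bh_adjust(ps) >= np.asarray(ps))
        assert bh_adjust([]).size == 0


# ---------------------------------------------------------------------------
# hypergeometric tail

class TestHypergeomTail:
    def test_examples(self):
        assert hypergeom_tail(0, 3, 3, 10) == 1.0
        assert hypergeom_tail(3, 3, 3, 10) == pytest.approx(1 / 120)
        assert hypergeom_tail(1, 2, 2, 4) == pytest.approx(5 / 6)

    def test_full_enumeration_small_universes(self):
        for N in (1, 2, 5, 9, 14):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        want = float(hypergeom_tail_exact(k, K, n, N))
                        assert hypergeom_tail(k, K, n, N) == pytest.approx(
                            want, abs=1e-12
                        ), (k, K, n, N)

    def test_inconsistent_counts(self):
        with pytest.raises(ValueError):
            hypergeom_tail(5, 3, 3, 10)
        with pytest.raises(ValueError):
            hypergeom_tail(1, 11, 3, 10)


# ---------------------------------------------------------------------------
# correlation, t test, chi-square

class TestPearson:
    def test_perfect_correlations(self):
        x = [1.0, 2.0, 4.0, 8.0, 9.0]
        assert pearson(x, x)[0] == pytest.approx(1.0)
        assert pearson(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_formula_oracle(self):
        x, y = [1, 2, 3, 4], [1, 3, 2, 4]
        r, p = pearson(x, y)
        assert r == pytest.approx(0.8)
        # two-sided p via the t transform, df = n - 2
        from scipy.stats import t as tdist

        tval = 0.8 * math.sqrt(2 / (1 - 0.64))
        assert p == pytest.approx(2 * tdist.sf(tval, 2), rel=1e-10)

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestTwoSampleT:
    def test_identical_groups(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0) and res.p_value == pytest.approx(1.0)

    def test_zero_within_group_variance(self):
        res = two_sample_t([0.0, 0.0], [1.0, 1.0])
        assert res.degenerate and res.p_value < 1e-250

    def test_welch_formula(self):
        x, y = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
        res = two_sample_t(x, y)
        se = math.sqrt(1.0 / 3 + 1.0 / 3)  # both sample variances are 1
        assert res.statistic == pytest.approx(-1.0 / se)
        assert res.statistic == pytest.approx(-1.224744871, abs=1e-8)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [1.0, 2.0])


class TestChiSquare2x2:
    def test_independence(self):
        res = chi_square_2x2(10, 10, 10, 10)
        assert res.statistic == pytest.approx(0.0) and res.p_value == pytest.approx(1.0)

    def test_formula_oracle(self):
        assert chi_square_2x2(20, 10, 10, 20).statistic == pytest.approx(20 / 3)
        assert chi_square_2x2(1, 0, 0, 1).statistic == pytest.approx(2.0)

    def test_zero_margin(self):
        with pytest.raises(ValueError):
            chi_square_2x2(0, 0, 5, 5)


# ---------------------------------------------------------------------------
# survival primitives

class TestKMCurve:
    def test_all_events_quarter_drops(self):
        km = km_curve([1, 2, 3, 4], [1, 1, 1, 1])
        for t, s in [(1, 0.75), (2, 0.5), (3, 0.25), (4, 0.0)]:
            assert km(t) == pytest.approx(s)

    def test_all_censored_flat(self):
        km = km_curve([1, 2, 3], [0, 0, 0])
        assert km(3) == 1.0

    def test_product_limit_with_censoring(self):
        # hand computation (events take precedence at tied times):
        # t=1: 4 at risk, 1 event -> 3/4; t=2: 3 at risk, 1 event -> 3/4*2/3=1/2
        # (the censored subject leaves without a drop); t=3: 1 at risk -> 0
        km = km_curve([1, 2, 2, 3], [1, 0, 1, 1])
        assert km(1) == pytest.approx(0.75)
        assert km(2) == pytest.approx(0.5)
        assert km(3) == pytest.approx(0.0)

    def test_total_drop_iff_all_events(self):
        assert km_curve([1, 5, 9], [1, 1, 1])(9) == pytest.approx(0.0)
        assert km_curve([1, 5, 9], [1, 1, 0])(9) > 0.0

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_curve([-1, 2], [1, 1])


class TestLogrank:
    def test_identical_groups_null(self):
        g = ([1.0, 2.0, 3.0], [1, 1, 1])
        res = logrank_test([g, g])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_two_groups(self):
        # A: 5 events at t=1; B: 5 censored at t=2.  Single event time t=1:
        # O_A=5, E_A=5*(5/10)=2.5, Var=5*(5/10)*(5/10)*(10-5)/(10-1)=25/36
        # chi2 = (5-2.5)^2 / (25/36) = 9.0
        a = ([1.0] * 5, [1] * 5)
        b = ([2.0] * 5, [0] * 5)
        res = logrank_test([a, b])
        assert res.statistic == pytest.approx(9.0)

    def test_no_events_degenerate(self):
        res = logrank_test([([1.0, 2.0], [0, 0]), ([3.0], [0])])
        assert res.degenerate and res.p_value == 1.0

    def test_three_groups_df2(self):
        from scipy.stats import chi2 as chi2_dist

        rng = np.random.default_rng(17)
        groups = [
            (rng.exponential(10, size=12), np.ones(12)),
            (rng.exponential(10, size=12), np.ones(12)),
            (rng.exponential(30, size=12), np.zeros(12)),  # events-free but at risk
        ]
        res = logrank_test(groups)
        assert res.p_value == pytest.approx(
            float(chi2_dist.sf(res.statistic, 2)), rel=1e-9
        )

    def test_agrees_with_label_permutation(self):
        """Asymptotic p within Monte-Carlo error of a permutation p."""
        rng = np.random.default_rng(11)
        t1, t2 = rng.exponential(10, 12), rng.exponential(22, 12)
        e = np.ones(12)
        obs = logrank_test([(t1, e), (t2, e)]).statistic
        pooled = np.concatenate([t1, t2])
        count = 0
        n_perm = 1000
        for _ in range(n_perm):
            perm = rng.permutation(24)
            stat = logrank_test([(pooled[perm[:12]], e), (pooled[perm[12:]], e)]).statistic
            count += stat >= obs
        p_perm = (1 + count) / (1 + n_perm)
        p_asym = logrank_test([(t1, e), (t2, e)]).p_value
        assert abs(p_perm - p_asym) < 3 * math.sqrt(p_perm * (1 - p_perm) / n_perm) + 0.02
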