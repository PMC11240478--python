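"""The Wilcoxon signed-rank implementation against its independent oracle.

The brute-force oracle enumerates every sign vector explicitly; the main
path uses a dynamic program over achievable rank sums.  scipy's wilcoxon is
a second, external cross-check on the approximation path.
"""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from scipy import stats

from thzcontrast import (
    Method,
    exact_null_distribution,
    normal_approx_p,
    oracle_p,
    signed_rank_test,
)


def from_differences(d):
    """Paired series (d, 0) realizing a given difference vector."""
    d = np.asarray(d, dtype=float)
    return d, np.zeros_like(d)


class TestExactNullDistribution:
    def test_n1(self):
        assert exact_null_distribution(1) == {0: 0.5, 1: 0.5}

    def test_n3_masses(self):
        # enumerating the 8 subsets of {1,2,3}: sums 0,1,2,3,3,4,5,6
        dist = exact_null_distribution(3)
        assert dist[3] == pytest.approx(0.25)
        for w in (0, 1, 2, 4, 5, 6):
            assert dist[w] == pytest.approx(0.125)

    @pytest.mark.parametrize("n", [2, 7, 14, 25])
    def test_normalized_and_symmetric(self, n):
        dist = exact_null_distribution(n)
        total = n * (n + 1) // 2
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)
        for w, p in dist.items():
            assert p == pytest.approx(dist[total - w])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            exact_null_distribution(0)
        with pytest.raises(ValueError):
            exact_null_distribution(26)


class TestSignedRankTest:
    def test_all_zero_differences_degenerate(self):
        x = np.arange(10.0)
        res = signed_rank_test(x, x)
        assert res.method is Method.DEGENERATE
        assert res.n_effective == 0
        assert res.p_value == 1.0

    def test_forced_exact_value_monotone_differences(self):
        # differences 1..5, all positive: W- = 0, two-sided p = 2/32
        res = signed_rank_test(*from_differences([1, 2, 3, 4, 5]))
        assert res.w_minus == 0.0
        assert res.method is Method.EXACT
        assert res.p_value == 0.0625

    def test_forced_exact_value_mixed_signs(self):
        res = signed_rank_test(*from_differences([1, -2, 3, -4, 5]))
        assert (res.w_plus, res.w_minus, res.statistic) == (9.0, 6.0, 6.0)
        assert res.p_value == 0.8125

    def test_input_validation(self):
        with pytest.raises(ValueError):
            signed_rank_test([1.0, 2.0], [1.0])
        with pytest.raises(ValueError):
            signed_rank_test([1.0], [2.0])
        with pytest.raises(ValueError):
            signed_rank_test([1.0, np.nan], [0.0, 0.0])

    def test_rank_sum_identity_with_ties(self):
        """w_plus + w_minus = n(n+1)/2 even under midranks."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            d = rng.integers(-3, 4, size=12).astype(float)
            res = signed_rank_test(*from_differences(d))
            n = res.n_effective
            if n:
                assert res.w_plus + res.w_minus == pytest.approx(n * (n + 1) / 2)
            assert res.statistic == min(res.w_plus, res.w_minus)
            assert 0.0 <= res.p_value <= 1.0

    def test_tied_small_sample_matches_oracle(self):
        res = signed_rank_test(*from_differences([1, 1, -1]))
        assert res.p_value == oracle_p([1, 1, -1])

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=15), rng.normal(size=15)
        a, b = signed_rank_test(x, y), signed_rank_test(y, x)
        assert a.p_value == b.p_value
        assert (a.w_plus, a.w_minus) == (b.w_minus, b.w_plus)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=-10, max_value=10, allow_nan=False),
            min_size=3,
            max_size=12,
        ),
        st.floats(min_value=0.01, max_value=5.0),
    )
    def test_location_shift_never_increases_w_minus(self, diffs, shift):
        """Shifting x upward can only move rank mass off the negative side.

        Holds for zero-free differences; a zero pair re-entering the sample
        after the shift can add a (small) negative rank, so those inputs are
        excluded.
        """
        assume(all(d != 0 and d + shift != 0 for d in diffs))
        x, y = from_differences(diffs)
        before = signed_rank_test(x, y)
        after = signed_rank_test(x + shift, y)
        assert after.w_minus <= before.w_minus + 1e-9

    def test_large_sample_uses_normal_approx(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=60)
        y = rng.normal(size=60)
        res = signed_rank_test(x, y)
        assert res.method is Method.NORMAL_APPROX
        # external cross-check: scipy's approximation with continuity correction
        ref = stats.wilcoxon(x, y, mode="approx", correction=True)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)


class TestOracle:
    def test_known_values(self):
        assert oracle_p([1, 2, 3, 4, 5]) == 0.0625
        assert oracle_p([5.0]) == 1.0  # single pair: both tails cover all mass

    def test_rejects_large_n(self):
        with pytest.raises(ValueError, match="oracle"):
            oracle_p(np.arange(1.0, 16.0))

    def test_oracle_equivalence_random_tie_free(self):
        """Main DP path equals brute-force enumeration exactly, 300 vectors."""
        rng = np.random.default_rng(2024)
        for _ in range(300):
            n = int(rng.integers(3, 13))
            d = rng.normal(size=n)
            d = d[d != 0]
            if np.unique(np.abs(d)).size < d.size or d.size < 2:
                continue
            res = signed_rank_test(*from_differences(d))
            assert res.method is Method.EXACT
            assert res.p_value == oracle_p(d)


class TestNormalApprox:
    def test_at_null_mean_p_is_one(self):
        n = 12
        assert normal_approx_p(n * (n + 1) / 4.0, n) == 1.0

    def test_rejects_small_n(self):
        with pytest.raises(ValueError):
            normal_approx_p(10.0, 9)

    def test_extreme_statistic_vs_monte_carlo(self):
        # n=30, all differences positive: compare against sign-permutation MC
        n = 30
        w_plus = n * (n + 1) / 2.0
        p = normal_approx_p(w_plus, n)
        assert p < 0.001
        rng = np.random.default_rng(3)
        ranks = np.arange(1.0, n + 1)
        total = ranks.sum()
        signs = rng.choice([0.0, 1.0], size=(100_000, n))
        w = signs @ ranks
        mc = np.mean(np.minimum(w, total - w) <= min(w_plus, total - w_plus))
        assert p == pytest.approx(mc, abs=1e-3)

    def test_close_to_exact_at_n20(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            d = rng.normal(size=20)
            res_exact = signed_rank_test(*from_differences(d))
            assert res_exact.method is Method.EXACT
            p_approx = normal_approx_p(res_exact.w_plus, res_exact.n_effective)
            assert abs(p_approx - res_exact.p_value) < 0.01


def test_null_calibration_exact_test_is_conservative():
    """Under a symmetric null at small n, rejection at 0.05 lies in [0.03, 0.06]."""
    rng = np.random.default_rng(8)
    n_reps = 2500
    rej = 0
    for _ in range(n_reps):
        d = rng.normal(size=18)
        rej += signed_rank_test(*from_differences(d)).p_value < 0.05
    assert 0.03 <= rej / n_reps <= 0.06
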