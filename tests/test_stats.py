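"""Exact rank tests against brute-force enumeration oracles."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu, wilcoxon

from cardiomea.stats import mann_whitney_u, wilcoxon_signed_rank


def brute_force_mwu_p(x, y):
    """Two-sided exact p by enumerating every group labeling."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    nx = len(x)

    def u_stat(ix):
        xs = pooled[list(ix)]
        ys = np.delete(pooled, list(ix))
        gt = sum((a > b) + 0.5 * (a == b) for a in xs for b in ys)
        return gt

    u_obs = u_stat(range(nx))
    dist = [u_stat(ix) for ix in combinations(range(len(pooled)), nx)]
    dist = np.asarray(dist)
    lo = np.mean(dist <= u_obs + 1e-9)
    hi = np.mean(dist >= u_obs - 1e-9)
    return min(1.0, 2 * min(lo, hi))


def brute_force_wilcoxon_p(before, after):
    d = np.asarray(after, float) - np.asarray(before, float)
    d = d[d != 0]
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    dist = []
    for mask in range(2**n):
        signs = [(mask >> i) & 1 for i in range(n)]
        dist.append(sum(r for r, s in zip(ranks, signs) if s))
    dist = np.asarray(dist, float)
    lo = np.mean(dist <= w_obs + 1e-9)
    hi = np.mean(dist >= w_obs - 1e-9)
    return min(1.0, 2 * min(lo, hi))


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.1)

    def test_identical_multisets_symmetry(self):
        res = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(9 / 2)
        assert res.p_value == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_equals_full_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        nx, ny = rng.integers(2, 7), rng.integers(2, 7)
        x = rng.permutation(np.arange(nx + ny, dtype=float) * 1.7)[:nx]
        y = rng.normal(size=ny) + np.arange(ny) * 10  # distinct values
        res = mann_whitney_u(x, y)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(brute_force_mwu_p(x, y))

    @pytest.mark.parametrize("seed", range(3))
    def test_exact_p_matches_scipy(self, seed):
        rng = np.random.default_rng(seed + 50)
        x = rng.normal(size=5)
        y = rng.normal(size=6) + 0.5
        ours = mann_whitney_u(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert ours.p_value == pytest.approx(ref.pvalue)

    def test_p_monotone_under_group_shift(self):
        """Pushing one group further away never increases the exact p."""
        rng = np.random.default_rng(9)
        x = rng.normal(size=5)
        y0 = rng.normal(size=5)
        ps = [mann_whitney_u(x, y0 + shift).p_value for shift in (0.0, 1.0, 2.0, 4.0, 8.0)]
        assert all(b <= a + 1e-12 for a, b in zip(ps, ps[1:]))

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=30), rng.normal(size=30) + 1
        res = mann_whitney_u(x, y)
        assert res.method == "normal"
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res.p_value == pytest.approx(ref.pvalue, rel=0.05)


class TestWilcoxon:
    def test_all_positive_differences(self):
        before = np.zeros(5)
        after = np.arange(1.0, 6.0)
        res = wilcoxon_signed_rank(before, after)
        assert res.statistic == 15.0
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 / 32)

    def test_no_change_is_degenerate(self):
        res = wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert res.degenerate
        assert res.p_value == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_p_equals_sign_enumeration(self, seed):
        rng = np.random.default_rng(seed + 10)
        n = int(rng.integers(4, 9))
        before = rng.normal(size=n)
        after = before + rng.normal(size=n) * 2 + 0.3
        res = wilcoxon_signed_rank(before, after)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(brute_force_wilcoxon_p(before, after))

    def test_exact_p_matches_scipy(self):
        rng = np.random.default_rng(60)
        before = rng.normal(size=8)
        after = before + rng.normal(size=8) + 0.8
        ours = wilcoxon_signed_rank(before, after)
        ref = wilcoxon(after - before, alternative="two-sided", mode="exact")
        assert ours.p_value == pytest.approx(ref.pvalue)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0], [1.0, 2.0])


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    x=st.lists(st.integers(0, 40), min_size=2, max_size=5),
    shift=st.integers(0, 60),
)
def test_mwu_p_in_unit_interval_and_shift_invariant(x, shift):
    """p lies in (0, 1] and is invariant to common location shifts."""
    y = [v + 1 for v in x[::-1]]
    a = mann_whitney_u(x, y)
    b = mann_whitney_u([v + shift for v in x], [v + shift for v in y])
    assert 0 < a.p_value <= 1
    assert a.p_value == pytest.approx(b.p_value)
    assert a.statistic == pytest.approx(b.statistic)
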