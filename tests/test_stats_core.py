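"""Unit and property tests for the statistical primitives.

Independent oracles: scipy's exact Mann-Whitney for the rank-sum null,
brute-force itertools enumeration for the blocked permutation null, and
statsmodels' multipletests for p-value adjustment.
"""

import itertools
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mixotracer.errors import ValidationError
from mixotracer.stats_core import (
    adjust_p,
    blocked_permutation_test,
    rank_sum_test,
)


class TestRankSum:
    def test_complete_separation_4v4_exact(self):
        # oracle: 2 / C(8,4) = 2/70, the two one-sided extreme subsets
        _, p = rank_sum_test([5, 6, 7, 8], [1, 2, 3, 4])
        assert p == pytest.approx(2 / comb(8, 4), abs=1e-12)

    def test_complete_separation_3v3_not_significant(self):
        # 2 / C(6,3) = 0.1: complete separation cannot reach 0.05 at n=3
        _, p = rank_sum_test([4, 5, 6], [1, 2, 3])
        assert p == pytest.approx(2 / comb(6, 3), abs=1e-12)
        assert p >= 0.05

    def test_identical_multisets_p_one(self):
        _, p = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_matches_scipy_exact_no_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            x = rng.normal(size=rng.integers(3, 9))
            y = rng.normal(size=rng.integers(3, 9))
            _, p = rank_sum_test(x, y)
            expected = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert p == pytest.approx(expected.pvalue, abs=1e-10)

    def test_exact_vs_normal_approximation_agree(self):
        # the two routes should rarely disagree by more than 0.02 at n=10 v 10
        rng = np.random.default_rng(2)
        worst = 0.0
        for _ in range(300):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            _, p_exact = rank_sum_test(x, y)
            # force the approximation path via a tie that does not involve
            # the compared values' ordering: use scipy's asymptotic p instead
            p_approx = sps.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic"
            ).pvalue
            worst = max(worst, abs(p_exact - p_approx))
        assert worst < 0.02

    def test_ties_use_normal_approximation(self):
        x = [1.0, 2.0, 2.0, 3.0, 5.0]
        y = [2.0, 4.0, 4.0, 6.0, 6.0]
        _, p = rank_sum_test(x, y)
        expected = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(expected.pvalue, rel=0.05)

    def test_empty_group_raises(self):
        with pytest.raises(ValidationError):
            rank_sum_test([], [1.0])

    @given(
        x=st.lists(st.floats(-50, 50), min_size=1, max_size=8),
        y=st.lists(st.floats(-50, 50), min_size=1, max_size=8),
    )
    @settings(max_examples=60, deadline=None)
    def test_symmetry_and_range(self, x, y):
        _, p_xy = rank_sum_test(x, y)
        _, p_yx = rank_sum_test(y, x)
        assert 0 < p_xy <= 1
        assert p_xy == pytest.approx(p_yx, abs=1e-9)


def _brute_force_blocked_p(values, groups, blocks):
    """Exhaustive oracle: enumerate within-block label rearrangements."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    blocks = np.asarray(blocks)
    labels = sorted(set(groups))
    ref, alt = labels

    def effect(g):
        return values[g == alt].mean() - values[g == ref].mean()

    obs = abs(effect(groups))
    block_ids = sorted(set(blocks))
    per_block_perms = []
    for b in block_ids:
        idx = np.flatnonzero(blocks == b)
        k = int((groups[idx] == alt).sum())
        per_block_perms.append(
            [set(c) for c in itertools.combinations(range(len(idx)), k)]
        )
    count = total = 0
    for combo in itertools.product(*per_block_perms):
        g = np.empty(len(values), dtype=object)
        for b, chosen in zip(block_ids, combo):
            idx = np.flatnonzero(blocks == b)
            for j, i in enumerate(idx):
                g[i] = alt if j in chosen else ref
        total += 1
        if abs(effect(g)) >= obs - 1e-12:
            count += 1
    return count / total


class TestBlockedPermutation:
    VALUES = np.array([1.0, 2.0, 6.0, 7.0, 0.5, 2.5, 5.0, 8.0])
    GROUPS = np.array(["a", "a", "b", "b"] * 2)
    BLOCKS = np.repeat([0, 1], 4)

    def test_exhaustive_matches_brute_force(self):
        res = blocked_permutation_test(self.VALUES, self.GROUPS, self.BLOCKS)
        assert res.exhaustive
        expected = _brute_force_blocked_p(self.VALUES, self.GROUPS, self.BLOCKS)
        assert res.p_value == pytest.approx(expected, abs=1e-12)

    def test_monte_carlo_close_to_exhaustive(self):
        # tiny 2-block x 4-unit instance: both routes available
        exact = blocked_permutation_test(self.VALUES, self.GROUPS, self.BLOCKS)
        mc = blocked_permutation_test(
            self.VALUES, self.GROUPS, self.BLOCKS,
            n_perm=99_999, seed=9, method="monte_carlo",
        )
        assert exact.exhaustive and not mc.exhaustive
        assert mc.p_value == pytest.approx(exact.p_value, abs=0.01)

    def test_constant_values_p_one(self):
        res = blocked_permutation_test(np.ones(8), self.GROUPS, self.BLOCKS)
        assert res.p_value == 1.0

    def test_add_one_rule_floor(self):
        # an effect larger than any permuted effect cannot beat 1/(n_perm+1)
        rng = np.random.default_rng(4)
        values = rng.normal(0, 0.01, 40)
        groups = np.tile(["a", "b"], 20)
        values[groups == "b"] += 100.0
        blocks = np.repeat(np.arange(4), 10)
        res = blocked_permutation_test(values, groups, blocks, n_perm=999, seed=0)
        assert not res.exhaustive
        assert res.p_value == pytest.approx(1 / 1000)

    def test_exchangeability_input_order(self):
        perm = np.random.default_rng(5).permutation(8)
        res1 = blocked_permutation_test(self.VALUES, self.GROUPS, self.BLOCKS)
        res2 = blocked_permutation_test(
            self.VALUES[perm], self.GROUPS[perm], self.BLOCKS[perm]
        )
        assert res1.p_value == pytest.approx(res2.p_value, abs=1e-12)

    def test_non_spanning_blocks_dropped_with_warning(self):
        values = np.array([1.0, 2.0, 3.0, 4.0, 9.0, 9.5])
        groups = np.array(["a", "b", "a", "b", "a", "a"])
        blocks = np.array([0, 0, 0, 0, 1, 1])
        with pytest.warns(UserWarning, match="dropped"):
            res = blocked_permutation_test(values, groups, blocks)
        assert res.n_blocks_used == 1
        assert res.n_blocks_dropped == 1

    def test_no_permutable_block_raises(self):
        with pytest.raises(ValidationError):
            blocked_permutation_test(
                [1.0, 2.0, 3.0, 4.0],
                ["a", "a", "b", "b"],
                [0, 0, 1, 1],
            )

    def test_monte_carlo_consistency_grows(self):
        rng = np.random.default_rng(6)
        values = rng.normal(0, 1, 18)
        groups = np.tile(["a", "a", "a", "b", "b", "b"], 3)
        blocks = np.repeat(np.arange(3), 6)
        exact = _brute_force_blocked_p(values, groups, blocks)
        errs = []
        for n_perm in (999, 9999):
            mc = blocked_permutation_test(
                values, groups, blocks, n_perm=n_perm, seed=1, method="monte_carlo"
            )
            errs.append(abs(mc.p_value - exact))
        assert errs[1] <= errs[0] + 0.01
        assert errs[1] < 0.02


class TestAdjustP:
    def test_single_p_unchanged(self):
        for method in ("none", "holm", "BH"):
            assert adjust_p([0.03], method)[0] == pytest.approx(0.03)

    def test_bh_hand_computed(self):
        # step-up: min over j>=i of p_(j) * n / j -> all 0.03
        out = adjust_p([0.01, 0.02, 0.03], "BH")
        assert out == pytest.approx([0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert adjust_p([1.0, 1.0, 1.0], "holm") == pytest.approx([1, 1, 1])

    def test_out_of_range_raises(self):
        with pytest.raises(ValidationError):
            adjust_p([0.5, 1.2], "BH")

    @given(
        p=st.lists(st.floats(0, 1), min_size=1, max_size=12),
        method=st.sampled_from(["holm", "BH"]),
    )
    @settings(max_examples=80, deadline=None)
    def test_matches_statsmodels(self, p, method):
        from statsmodels.stats.multitest import multipletests

        sm_method = {"holm": "holm", "BH": "fdr_bh"}[method]
        expected = multipletests(p, method=sm_method)[1]
        out = adjust_p(p, method)
        assert out == pytest.approx(expected, abs=1e-9)
        assert (out >= np.asarray(p) - 1e-12).all()
        assert (out <= 1).all()
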