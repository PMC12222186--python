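"""Gated test selection and the two from-scratch two-sample tests, each
checked against independent enumeration oracles and scipy cross-checks."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from saltmeta.binning import BinnedGroup
from saltmeta.compare import (
    TestKind as Chosen,
    Transform,
    compare_all_pairs,
    comparisons_table,
    mann_whitney_u,
    pair_seed,
    permutation_t_test,
    select_test,
)
from saltmeta.io import Setting


class TestSelectTest:
    def test_gaussian_equal_variance_selects_raw_permutation(self, rng):
        a = rng.normal(10, 2, 40)
        b = rng.normal(10, 2, 40)
        # oracle gates: both normal on raw scale, variances homogeneous
        assert stats.shapiro(a).pvalue > 0.05 and stats.shapiro(b).pvalue > 0.05
        assert stats.levene(a, b, center="median").pvalue > 0.05
        sel = select_test(a, b)
        assert sel.test is Chosen.PERMUTATION_T
        assert sel.transform is Transform.RAW

    def test_lognormal_selects_log_permutation(self, rng):
        a = rng.lognormal(0, 1, 60)
        b = rng.lognormal(0, 1, 60)
        assert min(stats.shapiro(a).pvalue, stats.shapiro(b).pvalue) <= 0.05
        la, lb = np.log(a), np.log(b)
        assert min(stats.shapiro(la).pvalue, stats.shapiro(lb).pvalue) > 0.05
        assert stats.levene(la, lb, center="median").pvalue > 0.05
        sel = select_test(a, b)
        assert sel.test is Chosen.PERMUTATION_T
        assert sel.transform is Transform.LOG

    def test_heavy_tails_fall_back_to_mann_whitney(self, rng):
        a = rng.standard_cauchy(60)
        b = rng.standard_cauchy(60)
        assert min(stats.shapiro(a).pvalue, stats.shapiro(b).pvalue) <= 0.05
        sel = select_test(a, b)
        assert sel.test is Chosen.MANN_WHITNEY
        # negative values: the log branch must have been skipped
        assert sel.gates.shapiro_log_p is None

    def test_unequal_variances_fall_back(self, rng):
        a = rng.normal(0, 1, 60)
        b = rng.normal(0, 6, 60)
        assert stats.levene(a, b, center="median").pvalue <= 0.05
        sel = select_test(a, b)
        assert sel.test is Chosen.MANN_WHITNEY

    def test_tiny_samples_go_to_mann_whitney(self):
        sel = select_test([1.0, 2.0], [3.0, 4.0])
        assert sel.test is Chosen.MANN_WHITNEY
        assert "small" in sel.note


def _brute_force_permutation_t(a, b):
    """Enumeration oracle: pooled-variance t over all label assignments,
    statistic computed by scipy."""
    pooled = np.concatenate([a, b])
    n, n_a = len(pooled), len(a)
    t_obs = stats.ttest_ind(a, b, equal_var=True).statistic
    count = total = 0
    for idx in itertools.combinations(range(n), n_a):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        t = stats.ttest_ind(pooled[mask], pooled[~mask], equal_var=True).statistic
        total += 1
        if abs(t) >= abs(t_obs) - 1e-12:
            count += 1
    return t_obs, count / total


class TestPermutationT:
    def test_two_vs_two_fixture_enumerates_to_one_third(self):
        res = permutation_t_test([1, 2], [10, 11])
        assert res.n_permutations == "exact"
        assert res.p_value == pytest.approx(2 / 6)

    def test_identical_samples_p_one(self):
        res = permutation_t_test([3.0, 4.0, 5.0], [3.0, 4.0, 5.0])
        assert res.p_value == pytest.approx(1.0)

    def test_zero_variance_equal_means(self):
        res = permutation_t_test([2.0, 2.0], [2.0, 2.0])
        assert res.p_value == 1.0

    def test_seed_reproducibility(self, rng):
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1, 30)
        r1 = permutation_t_test(a, b, n_resamples=999, seed=7)
        r2 = permutation_t_test(a, b, n_resamples=999, seed=7)
        assert r1.p_value == r2.p_value
        assert r1.n_permutations == 999

    @pytest.mark.parametrize("n_a,n_b", [(3, 3), (4, 4), (5, 5), (3, 5), (2, 4)])
    def test_exhaustive_agrees_with_enumeration_oracle(self, n_a, n_b, rng):
        a = rng.normal(0, 1, n_a)
        b = rng.normal(1, 1, n_b)
        res = permutation_t_test(a, b)
        t_oracle, p_oracle = _brute_force_permutation_t(a, b)
        assert res.n_permutations == "exact"
        assert res.statistic == pytest.approx(t_oracle)
        assert res.p_value == pytest.approx(p_oracle)

    def test_sampled_converges_to_exact(self, rng):
        a = rng.normal(0, 1, 6)
        b = rng.normal(0.8, 1, 6)
        exact = permutation_t_test(a, b).p_value
        B = 99999
        sampled = permutation_t_test(
            a, b, n_resamples=B, seed=3, enumeration_cap=1
        ).p_value
        se = math.sqrt(exact * (1 - exact) / B)
        assert abs(sampled - exact) <= 3 * se + 2 / B

    def test_sampled_p_never_zero(self, rng):
        a = rng.normal(0, 0.1, 20)
        b = rng.normal(50, 0.1, 20)
        res = permutation_t_test(a, b, n_resamples=499, seed=1, enumeration_cap=1)
        assert res.p_value >= 1 / 500

    def test_label_swap_symmetry(self, rng):
        a, b = rng.normal(0, 1, 5), rng.normal(1, 1, 5)
        assert permutation_t_test(a, b).p_value == pytest.approx(
            permutation_t_test(b, a).p_value
        )


def _brute_force_mw(a, b):
    """Rank-split enumeration oracle for tie-free data."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n, n_a, n_b = len(pooled), len(a), len(b)
    mu = n_a * n_b / 2.0
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0
    count = total = 0
    for idx in itertools.combinations(range(1, n + 1), n_a):
        u = sum(idx) - n_a * (n_a + 1) / 2.0
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return u_obs, count / total


class TestMannWhitney:
    def test_complete_separation_fixture(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.1)  # 2 / C(6,3)

    def test_swap_complements_u_and_preserves_p(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 6)
        r_ab = mann_whitney_u(a, b)
        r_ba = mann_whitney_u(b, a)
        assert r_ab.statistic + r_ba.statistic == pytest.approx(8 * 6)
        assert r_ab.p_value == pytest.approx(r_ba.p_value)

    def test_singleton_tie_half_u(self):
        res = mann_whitney_u([2.0], [2.0])
        assert res.statistic == pytest.approx(0.5)

    @pytest.mark.parametrize("n_a,n_b", [(3, 3), (4, 5), (5, 5), (2, 8), (4, 6)])
    def test_exact_matches_rank_split_enumeration(self, n_a, n_b, rng):
        a = rng.normal(0, 1, n_a)
        b = rng.normal(0.5, 1, n_b)
        res = mann_whitney_u(a, b)
        u_oracle, p_oracle = _brute_force_mw(a, b)
        assert res.method == "exact"
        assert res.statistic == pytest.approx(u_oracle)
        assert res.p_value == pytest.approx(p_oracle)

    def test_exact_matches_scipy_cross_check(self, rng):
        for _ in range(10):
            a = rng.normal(0, 1, 5)
            b = rng.normal(0.3, 1, 5)
            ours = mann_whitney_u(a, b)
            ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert ours.statistic == pytest.approx(ref.statistic)
            assert ours.p_value == pytest.approx(ref.pvalue)

    def test_normal_approximation_with_ties(self, rng):
        a = np.round(rng.normal(0, 1, 40), 1)
        b = np.round(rng.normal(0.5, 1, 40), 1)
        ours = mann_whitney_u(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert ours.method == "normal"
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-6)


def _group(bin_index, setting, values):
    v = np.asarray(values, dtype=float)
    return BinnedGroup(bin_index, setting, v, np.full_like(v, 5.0))


class TestCompareAllPairs:
    def test_three_settings_full_overlap_three_comparisons(self, rng):
        groups = [
            _group(0, s, rng.normal(0.5, 0.1, 12))
            for s in (Setting.FIELD, Setting.GREENHOUSE, Setting.OUTDOOR_POTS)
        ]
        results = compare_all_pairs(groups, "grain_yield", seed=0)
        assert len(results) == 3
        assert all(r.testable for r in results)
        table = comparisons_table(results)
        assert len(table) == 3 and table["p_value"].between(0, 1).all()

    def test_pair_without_shared_bins_is_untestable(self, rng):
        groups = [
            _group(0, Setting.FIELD, rng.normal(0.5, 0.1, 10)),
            _group(1, Setting.GREENHOUSE, rng.normal(0.5, 0.1, 10)),
        ]
        (res,) = compare_all_pairs(groups, "grain_yield", seed=0)
        assert not res.testable
        assert res.note == "no overlapping bins"

    def test_pools_across_overlapping_bins_only(self, rng):
        groups = [
            _group(0, Setting.FIELD, rng.normal(0.5, 0.1, 10)),
            _group(1, Setting.FIELD, rng.normal(0.4, 0.1, 10)),
            _group(1, Setting.GREENHOUSE, rng.normal(0.4, 0.1, 10)),
            _group(2, Setting.GREENHOUSE, rng.normal(0.3, 0.1, 10)),
        ]
        (res,) = compare_all_pairs(groups, "grain_yield", seed=0)
        assert res.bins_used == (1,)
        assert res.n_a == 10 and res.n_b == 10

    def test_pair_seed_is_stable_and_bounded(self):
        s1 = pair_seed(42, "grain_yield", Setting.FIELD, Setting.GREENHOUSE)
        s2 = pair_seed(42, "grain_yield", Setting.FIELD, Setting.GREENHOUSE)
        assert s1 == s2 and 0 <= s1 < 2**31
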