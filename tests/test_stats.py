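"""Hand-implemented tests vs worked examples and independent oracles."""

from itertools import combinations

import numpy as np
import pytest
from scipy.stats import kruskal, mannwhitneyu, rankdata, ttest_ind
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova
from statsmodels.stats.multitest import multipletests

from rtdysbiosis import (
    benjamini_hochberg,
    kruskal_wallis,
    one_way_anova,
    permanova,
    permanova_pairwise,
    wilcoxon_rank_sum,
)


def brute_force_rank_sum_p(x, y):
    """Two-sided p by enumerating every group assignment of the pooled data."""
    pooled = np.concatenate([x, y])
    m, N = len(x), len(pooled)
    ranks = rankdata(pooled)
    mu = m * (N + 1) / 2
    obs = abs(ranks[:m].sum() - mu)
    hits = total = 0
    for idx in combinations(range(N), m):
        total += 1
        if abs(ranks[list(idx)].sum() - mu) >= obs - 1e-12:
            hits += 1
    return hits / total


class TestWilcoxon:
    def test_worked_example_exact_p(self):
        # 2 of the 20 assignments are as extreme as (1,2,3) vs (4,5,6)
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], mode="exact")
        assert res.p_value == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups_p_one(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], mode="normal")
        assert res.p_value == pytest.approx(1.0, abs=0.05)

    def test_exact_matches_scipy_exact(self, rng):
        for _ in range(20):
            x = rng.normal(size=5)
            y = rng.normal(size=4)
            ours = wilcoxon_rank_sum(x, y, mode="exact").p_value
            ref = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_exact_close_to_normal_approximation(self, rng):
        for _ in range(50):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            p_exact = wilcoxon_rank_sum(x, y, mode="exact").p_value
            p_norm = wilcoxon_rank_sum(x, y, mode="normal").p_value
            assert abs(p_exact - p_norm) < 0.05

    def test_ties_fall_back_to_normal(self):
        res = wilcoxon_rank_sum([1, 2, 2], [2, 3, 4], mode="auto")
        assert res.method == "wilcoxon-normal"

    def test_exact_with_ties_rejected(self):
        with pytest.raises(ValueError, match="tie-free"):
            wilcoxon_rank_sum([1, 2, 2], [2, 3], mode="exact")

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            wilcoxon_rank_sum([], [1, 2])


class TestBenjaminiHochberg:
    def test_step_up_worked_example(self):
        q = benjamini_hochberg([0.005, 0.01, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.02, 0.02, 0.04, 0.04], atol=1e-12)

    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.037])[0] == pytest.approx(0.037)

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)

    def test_matches_statsmodels(self, rng):
        for _ in range(25):
            p = rng.uniform(size=rng.integers(1, 40))
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(benjamini_hochberg(p), ref, atol=1e-12)

    def test_monotone_in_p(self, rng):
        p = rng.uniform(size=30)
        q = benjamini_hochberg(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_order_invariance(self, rng):
        p = rng.uniform(size=15)
        perm = rng.permutation(15)
        np.testing.assert_allclose(
            benjamini_hochberg(p)[perm], benjamini_hochberg(p[perm]), atol=1e-12
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            benjamini_hochberg([0.5, 1.2])


class TestKruskalWallis:
    def test_worked_example_h(self):
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.statistic == pytest.approx(7.2, abs=1e-12)

    def test_all_identical_gives_null(self):
        res = kruskal_wallis([[5, 5], [5, 5, 5]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_two_groups_equals_wilcoxon_normal_no_continuity(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(size=7)
        p_kw = kruskal_wallis([x, y]).p_value
        p_w = wilcoxon_rank_sum(x, y, mode="normal", continuity=False).p_value
        assert p_kw == pytest.approx(p_w, abs=1e-6)

    def test_matches_scipy_with_ties(self, rng):
        groups = [rng.integers(0, 6, size=9).astype(float) for _ in range(3)]
        ours = kruskal_wallis(groups)
        ref = kruskal(*groups)
        assert ours.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            kruskal_wallis([[1, 2, 3]])


class TestAnova:
    def test_worked_example_f(self):
        # SS_between = 6 over 2 df, SS_within = 6 over 6 df -> F = 3
        # (cross-checked against scipy.stats.f_oneway)
        res = one_way_anova([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert res.statistic == pytest.approx(3.0, abs=1e-12)
        assert res.p_value == pytest.approx(0.125, abs=1e-10)

    def test_identical_groups_null(self):
        res = one_way_anova([[2, 2], [2, 2]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_two_groups_f_equals_t_squared(self, rng):
        x = rng.normal(size=9)
        y = rng.normal(size=6)
        f_res = one_way_anova([x, y])
        t_res = ttest_ind(x, y)
        assert f_res.statistic == pytest.approx(t_res.statistic**2, abs=1e-10)
        assert f_res.p_value == pytest.approx(t_res.pvalue, abs=1e-10)

    def test_degenerate_df_rejected(self):
        with pytest.raises(ValueError, match="degrees of freedom"):
            one_way_anova([[1.0], [2.0]])


def euclidean_dm(points):
    return np.linalg.norm(points[:, None] - points[None, :], axis=-1)


class TestPermanova:
    def test_p_floor_is_one_over_n_plus_one(self, rng):
        # two well-separated clusters, large enough that no permutation
        # recreates the observed partition by chance
        pts = np.vstack([rng.normal(0, 0.1, (10, 2)), rng.normal(50, 0.1, (10, 2))])
        labels = np.repeat(["a", "b"], 10)
        res = permanova(euclidean_dm(pts), labels, n_permutations=999, seed=7)
        assert res.p_value == pytest.approx(0.001)

    def test_statistic_matches_skbio(self, rng):
        pts = rng.normal(size=(12, 3))
        labels = np.repeat(["a", "b", "c"], 4)
        d = euclidean_dm(pts)
        ours = permanova(d, labels, n_permutations=99, seed=1)
        ref = skbio_permanova(
            DistanceMatrix(d, [str(i) for i in range(12)]), labels, permutations=99
        )
        assert ours.pseudo_f == pytest.approx(ref["test statistic"], abs=1e-10)

    def test_invariant_to_simultaneous_permutation(self, rng):
        pts = rng.normal(size=(10, 2))
        labels = np.array(list("aaabbbccca"))
        d = euclidean_dm(pts)
        perm = rng.permutation(10)
        a = permanova(d, labels, n_permutations=9, seed=3).pseudo_f
        b = permanova(d[np.ix_(perm, perm)], labels[perm], n_permutations=9, seed=3).pseudo_f
        assert a == pytest.approx(b, abs=1e-10)

    def test_duplicated_samples_in_both_groups_are_null(self, rng):
        pts = rng.normal(size=(8, 2))
        d = euclidean_dm(np.vstack([pts, pts]))
        labels = np.repeat(["a", "b"], 8)
        res = permanova(d, labels, n_permutations=199, seed=5)
        assert res.pseudo_f < 1e-10
        assert res.p_value > 0.5

    def test_fixed_seed_reproducible(self, rng):
        pts = rng.normal(size=(10, 2))
        labels = np.repeat(["a", "b"], 5)
        d = euclidean_dm(pts)
        p1 = permanova(d, labels, n_permutations=99, seed=11).p_value
        p2 = permanova(d, labels, n_permutations=99, seed=11).p_value
        assert p1 == p2

    def test_singleton_group_rejected(self, rng):
        d = euclidean_dm(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError, match="fewer than 2"):
            permanova(d, np.array(["a", "a", "a", "a", "b"]), n_permutations=9)

    def test_pairwise_covers_all_pairs_with_q(self, rng):
        pts = rng.normal(size=(12, 2))
        labels = np.repeat(["a", "b", "c"], 4)
        results = permanova_pairwise(euclidean_dm(pts), labels, n_permutations=99, seed=2)
        assert sorted(r.groups for r in results) == [("a", "b"), ("a", "c"), ("b", "c")]
        assert all(r.q_value is not None and r.q_value >= r.p_value - 1e-12 for r in results)
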