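"""Alpha diversity, depth scaling, generalized UniFrac and PCoA."""

import io as _io

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import procrustes
from skbio import TreeNode
from skbio.diversity import beta_diversity

from rtdysbiosis import (
    AbundanceTable,
    generalized_unifrac,
    normalize_to_max_depth,
    pcoa,
    rarefy,
    shannon_index,
)


def tree_from(newick: str) -> TreeNode:
    return TreeNode.read(_io.StringIO(newick))


def table_from(arr, taxa, samples, unit="proportions") -> AbundanceTable:
    return AbundanceTable(
        pd.DataFrame(np.asarray(arr, dtype=float), index=taxa, columns=samples),
        unit=unit,
    )


class TestShannon:
    @pytest.mark.parametrize("k", range(2, 11))
    def test_uniform_k_gives_ln_k(self, k):
        assert shannon_index(np.full(k, 1.0 / k)) == pytest.approx(np.log(k), abs=1e-12)

    def test_single_taxon_is_zero(self):
        assert shannon_index([0.0, 1.0, 0.0]) == 0.0

    def test_worked_example(self):
        # frozen from direct summation: -(0.5 ln 0.5 + 2 * 0.25 ln 0.25)
        assert shannon_index([0.5, 0.25, 0.25]) == pytest.approx(1.039721, abs=1e-6)

    def test_permutation_invariant(self, rng):
        p = rng.dirichlet(np.ones(20))
        assert shannon_index(p) == pytest.approx(
            shannon_index(rng.permutation(p)), abs=1e-12
        )

    def test_concentrating_mass_decreases_entropy(self):
        # move mass from a small to the largest component: majorization step
        p = np.array([0.5, 0.3, 0.2])
        q = np.array([0.6, 0.3, 0.1])
        assert shannon_index(q) < shannon_index(p)

    def test_log_base_conversion(self):
        assert shannon_index([0.5, 0.5], base=2) == pytest.approx(1.0, abs=1e-12)

    def test_negative_proportion_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            shannon_index([-0.1, 1.1])

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            shannon_index([0.5, 0.4])


class TestMaxDepthNormalization:
    def test_scale_factors_two_samples(self):
        t = table_from([[60, 80], [40, 120]], ["A", "B"], ["s1", "s2"], unit="counts")
        out = normalize_to_max_depth(t)
        np.testing.assert_allclose(out.values.sum(axis=0), [200.0, 200.0])
        np.testing.assert_allclose(out.values["s1"], [120.0, 80.0])

    def test_equal_depths_unchanged(self):
        t = table_from([[60, 80], [40, 20]], ["A", "B"], ["s1", "s2"], unit="counts")
        pd.testing.assert_frame_equal(normalize_to_max_depth(t).values, t.values)

    def test_three_depth_factors(self):
        # depths (50, 75, 150) -> factors (3, 2, 1)
        t = table_from(
            [[50, 75, 150]], ["A"], ["s1", "s2", "s3"], unit="counts"
        )
        out = normalize_to_max_depth(t)
        np.testing.assert_allclose(out.values.loc["A"], [150.0, 150.0, 150.0])

    def test_proportions_preserved(self, default_cohort):
        rel_before = default_cohort.table.relative_abundance()
        rel_after = normalize_to_max_depth(default_cohort.table).relative_abundance()
        np.testing.assert_allclose(
            rel_before.values.to_numpy(), rel_after.values.to_numpy(), atol=1e-12
        )

    def test_zero_depth_rejected(self):
        t = table_from([[0, 5]], ["A"], ["s1", "s2"], unit="counts")
        with pytest.raises(ValueError, match="s1"):
            normalize_to_max_depth(t)


class TestRarefy:
    def test_equalizes_depths(self, default_cohort):
        out = rarefy(default_cohort.table, seed=1)
        sums = out.values.sum(axis=0)
        assert sums.nunique() == 1

    def test_too_shallow_rejected(self, tiny_table):
        with pytest.raises(ValueError, match="shallower"):
            rarefy(tiny_table, depth=1000)


class TestGeneralizedUniFrac:
    @pytest.mark.parametrize("alpha", [0.0, 0.5, 1.0])
    def test_identical_samples_distance_zero(self, alpha, rng):
        tree = tree_from("((A:1,B:2):0.5,(C:0.3,D:0.7):1.1);")
        p = rng.dirichlet(np.ones(4))
        t = table_from(np.column_stack([p, p]), list("ABCD"), ["s1", "s2"])
        dm = generalized_unifrac(t, tree, alpha=alpha)
        assert dm["s1", "s2"] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("alpha", [0.0, 0.5, 1.0])
    def test_disjoint_two_tip_distance_one(self, alpha):
        tree = tree_from("(A:1,B:1);")
        t = table_from([[1, 0], [0, 1]], ["A", "B"], ["s1", "s2"])
        dm = generalized_unifrac(t, tree, alpha=alpha)
        assert dm["s1", "s2"] == pytest.approx(1.0, abs=1e-12)

    def test_alpha_one_matches_weighted_normalized_unifrac(self, rng):
        """alpha=1 equals weighted-normalized UniFrac (independent oracle)."""
        for _ in range(5):
            n_tips = 8
            taxa = [f"t{i}" for i in range(n_tips)]
            nodes = [TreeNode(name=t, length=float(rng.exponential(0.3))) for t in taxa]
            while len(nodes) > 1:
                i, j = sorted(rng.choice(len(nodes), 2, replace=False))
                b, a = nodes.pop(int(j)), nodes.pop(int(i))
                nodes.append(
                    TreeNode(length=float(rng.exponential(0.3)), children=[a, b])
                )
            tree = nodes[0]
            tree.length = None
            counts = rng.integers(0, 50, size=(4, n_tips))
            counts[:, 0] += 1  # no empty sample
            props = counts / counts.sum(axis=1, keepdims=True)
            t = table_from(props.T, taxa, [f"s{i}" for i in range(4)])
            ours = generalized_unifrac(t, tree, alpha=1.0)
            ref = beta_diversity(
                "weighted_unifrac",
                counts,
                ids=[f"s{i}" for i in range(4)],
                taxa=taxa,
                tree=tree,
                normalized=True,
            )
            np.testing.assert_allclose(ours.data, ref.data, atol=1e-10)

    def test_distances_lie_in_unit_interval(self, rng):
        tree = tree_from("((A:1,B:2):0.5,(C:0.3,D:0.7):1.1);")
        props = rng.dirichlet(np.ones(4), size=6).T
        t = table_from(props, list("ABCD"), [f"s{i}" for i in range(6)])
        dm = generalized_unifrac(t, tree, alpha=0.5)
        assert np.all(dm.data >= 0) and np.all(dm.data <= 1 + 1e-12)
        np.testing.assert_allclose(dm.data, dm.data.T, atol=1e-12)

    def test_tip_relabeling_consistency(self, rng):
        """Permuting taxa rows together with tip labels leaves distances fixed."""
        tree_a = tree_from("((A:1,B:2):0.5,(C:0.3,D:0.7):1.1);")
        tree_b = tree_from("((C:1,D:2):0.5,(A:0.3,B:0.7):1.1);")
        props = rng.dirichlet(np.ones(4), size=3).T
        t_a = table_from(props, list("ABCD"), ["s1", "s2", "s3"])
        t_b = table_from(props, list("CDAB"), ["s1", "s2", "s3"])
        np.testing.assert_allclose(
            generalized_unifrac(t_a, tree_a).data,
            generalized_unifrac(t_b, tree_b).data,
            atol=1e-12,
        )

    def test_taxon_absent_from_tree_named(self):
        tree = tree_from("(A:1,B:1);")
        t = table_from([[0.5, 0.5], [0.3, 0.2], [0.2, 0.3]], ["A", "B", "X"], ["s1", "s2"])
        with pytest.raises(ValueError, match="X"):
            generalized_unifrac(t, tree)


class TestPCoA:
    def test_recovers_planted_euclidean_configuration(self, rng):
        pts = rng.normal(size=(6, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        ords = pcoa(d, n_components=2)
        _, _, disparity = procrustes(pts, ords.coordinates.to_numpy())
        assert disparity < 1e-8

    def test_all_zero_distances_give_zero_coordinates(self):
        with pytest.warns(UserWarning, match="positive eigenvalue"):
            ords = pcoa(np.zeros((4, 4)), n_components=2)
        np.testing.assert_allclose(ords.coordinates.to_numpy(), 0.0)

    def test_eigenvalues_non_increasing_and_positive(self, default_cohort, rng):
        pts = rng.normal(size=(10, 4))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        ords = pcoa(d, n_components=4)
        assert np.all(np.diff(ords.eigenvalues) <= 1e-12)
        assert np.all(ords.eigenvalues > 0)

    def test_matches_skbio_pcoa(self, rng):
        from skbio import DistanceMatrix
        from skbio.stats.ordination import pcoa as skbio_pcoa

        pts = rng.normal(size=(8, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        ids = [f"s{i}" for i in range(8)]
        ours = pcoa(DistanceMatrix(d, ids), n_components=3)
        ref = skbio_pcoa(DistanceMatrix(d, ids), number_of_dimensions=3)
        np.testing.assert_allclose(
            ours.eigenvalues, ref.eigvals.to_numpy()[:3], atol=1e-8
        )
        np.testing.assert_allclose(
            np.abs(ours.coordinates.to_numpy()),
            np.abs(ref.samples.to_numpy()[:, :3]),
            atol=1e-6,
        )
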