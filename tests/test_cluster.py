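import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from sklearn.metrics import adjusted_rand_score

from spinephys import synthetic as syn
from spinephys.cluster import (assemble_feature_table, cluster_purity,
                               cut_tree, export_dendrogram_newick,
                               minmax_normalize, silhouette_select_k,
                               ward_linkage)
from spinephys.core import FeatureTable
from tests.oracles import brute_force_ward


def assert_tree_matches_oracle(x):
    tree = ward_linkage(x)
    oracle = brute_force_ward(x)
    got = np.array(sorted(
        (sorted(row[:2]) + [row[2], row[3]] for row in tree.linkage),
        key=lambda r: r[2]))
    exp = np.array(sorted(
        (sorted(row[:2]) + [row[2], row[3]] for row in oracle),
        key=lambda r: r[2]))
    np.testing.assert_allclose(got, exp, atol=1e-8)


class TestAssembleFeatureTable:
    RECORDS = {
        "a": {"cm_pf": 10.0, "adaptation": 0.5},
        "b": {"cm_pf": 14.0, "adaptation": 0.9},
        "c": {"cm_pf": 12.0},
    }

    def test_missing_value_imputed_with_median(self):
        t = assemble_feature_table(self.RECORDS, ["cm_pf", "adaptation"])
        i = t.cell_ids.index("c")
        j = t.feature_names.index("adaptation")
        assert t.values[i, j] == pytest.approx(0.7)
        assert t.mask[i, j]

    def test_complete_features_untouched(self):
        t = assemble_feature_table(self.RECORDS, ["cm_pf"])
        assert not t.mask.any()
        assert sorted(t.values[:, 0]) == [10.0, 12.0, 14.0]

    def test_feature_absent_everywhere_is_error(self):
        with pytest.raises(ValueError):
            assemble_feature_table(self.RECORDS, ["cm_pf", "nonexistent"])


class TestMinmaxNormalize:
    def table(self, cols):
        arr = np.asarray(cols, float).T
        return FeatureTable([f"c{i}" for i in range(arr.shape[0])],
                            [f"f{j}" for j in range(arr.shape[1])], arr)

    def test_column_mapped_to_unit_interval(self):
        out = minmax_normalize(self.table([[2.0, 4.0, 6.0]]))
        np.testing.assert_allclose(out.values[:, 0], [0.0, 0.5, 1.0])

    def test_constant_column_maps_to_half_with_warning(self):
        with pytest.warns(UserWarning):
            out = minmax_normalize(self.table([[3.0, 3.0, 3.0]]))
        np.testing.assert_allclose(out.values[:, 0], 0.5)

    def test_idempotent_on_unit_interval_data(self):
        once = minmax_normalize(self.table([[0.0, 0.25, 1.0]]))
        twice = minmax_normalize(once)
        np.testing.assert_allclose(once.values, twice.values)


class TestWardLinkage:
    def test_one_dimensional_points_merge_nearest_first(self):
        """Points {0, 1, 10}: the first merge joins 0 and 1 at height 1.0."""
        tree = ward_linkage(np.array([[0.0], [1.0], [10.0]]))
        assert sorted(tree.linkage[0, :2]) == [0, 1]
        assert tree.linkage[0, 2] == pytest.approx(1.0)

    def test_identical_points_merge_at_zero_height(self):
        tree = ward_linkage(np.array([[2.0, 2.0], [2.0, 2.0], [5.0, 0.0]]))
        assert tree.linkage[0, 2] == pytest.approx(0.0)

    def test_six_point_instance_matches_exhaustive_oracle(self, rng):
        assert_tree_matches_oracle(rng.standard_normal((6, 2)))

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_random_instances_match_exhaustive_oracle(self, seed):
        """The linkage agrees with greedy SSE-increase enumeration on
        random instances with up to 8 points."""
        r = np.random.default_rng(seed)
        n = int(r.integers(2, 9))
        d = int(r.integers(1, 4))
        assert_tree_matches_oracle(r.standard_normal((n, d)))


class TestCutTree:
    @pytest.fixture()
    def tree(self):
        return ward_linkage(np.array([[0.0], [1.0], [10.0]]))

    def test_k1_single_label(self, tree):
        assert len(set(cut_tree(tree, 1))) == 1

    def test_kn_all_distinct(self, tree):
        assert len(set(cut_tree(tree, 3))) == 3

    def test_k2_partition_matches_oracle(self, tree):
        labels = cut_tree(tree, 2)
        assert labels[0] == labels[1] != labels[2]

    def test_out_of_range_k_rejected(self, tree):
        with pytest.raises(ValueError):
            cut_tree(tree, 0)
        with pytest.raises(ValueError):
            cut_tree(tree, 4)


class TestSilhouetteSelectK:
    def test_two_separated_blobs_give_k2(self, rng):
        x = np.vstack([rng.normal(0, 1, (40, 3)), rng.normal(12, 1, (40, 3))])
        res = silhouette_select_k(x)
        assert res.chosen_k == 2
        assert all(-1.0 <= s <= 1.0 for k in res.silhouettes
                   for s in res.silhouettes[k])

    def test_four_planted_blobs_recovered_exactly(self):
        table, truth = syn.synthesize_feature_table(
            4, 40, separation=8.0, within_sd=1.0, n_features=10, seed=5)
        norm = minmax_normalize(table)
        res = silhouette_select_k(norm.values)
        assert res.chosen_k == 4
        assert adjusted_rand_score(truth.cluster_labels, res.labels[4]) == 1.0

    def test_single_blob_takes_fallback_path(self, rng):
        x = rng.normal(0, 1, (30, 4))
        res = silhouette_select_k(x)
        assert res.fallback or res.chosen_k == 1
        assert res.flags

    def test_chosen_k_stable_under_row_permutation(self, rng):
        table, _ = syn.synthesize_feature_table(
            3, 20, separation=8.0, within_sd=1.0, n_features=10, seed=8)
        x = minmax_normalize(table).values
        base = silhouette_select_k(x).chosen_k
        perm = rng.permutation(x.shape[0])
        assert silhouette_select_k(x[perm]).chosen_k == base

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            silhouette_select_k(np.zeros((2, 2)))


class TestNewickExport:
    def test_two_leaves_midpoint_convention(self):
        tree = ward_linkage(np.array([[0.0], [1.0]]))
        assert export_dendrogram_newick(tree, ["A", "B"]) == "(A:0.5,B:0.5);"

    def test_three_leaf_tree_round_trips_through_parser(self):
        import skbio
        tree = ward_linkage(np.array([[0.0], [1.0], [10.0]]))
        nwk = export_dendrogram_newick(tree, ["A", "B", "C"])
        parsed = skbio.TreeNode.read([nwk])
        assert sorted(t.name for t in parsed.tips()) == ["A", "B", "C"]
        # ultrametric: every leaf sits at the same depth (root height / 2)
        depths = {t.name: parsed.distance(t) for t in parsed.tips()}
        assert max(depths.values()) == pytest.approx(min(depths.values()))

    def test_metacharacters_in_leaf_names_quoted(self):
        import skbio
        tree = ward_linkage(np.array([[0.0], [1.0]]))
        nwk = export_dendrogram_newick(tree, ["PN:1", "UN 2"])
        parsed = skbio.TreeNode.read([nwk])
        assert sorted(t.name for t in parsed.tips()) == ["PN:1", "UN 2"]


class TestClusterPurity:
    def test_pure_cluster_is_100_percent(self):
        labels = np.zeros(40, dtype=int)
        purity = cluster_purity(labels, ["SPBN"] * 40)
        assert purity[0] == pytest.approx(1.0)

    def test_mixed_cluster_fraction(self):
        """17 SPBN / 13 UN in one cluster: purity 17/30 = 56.7 %."""
        labels = np.zeros(30, dtype=int)
        purity = cluster_purity(labels, ["SPBN"] * 17 + ["UN"] * 13)
        assert purity[0] == pytest.approx(17.0 / 30.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cluster_purity(np.zeros(3, dtype=int), ["SPBN"] * 2)
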