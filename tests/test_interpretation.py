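"""Importance ranking, prediction profiles, hierarchical clustering."""

import numpy as np
import pandas as pd
import pytest

from tml import (
    ConfigurationError,
    LearnerSpec,
    ProfileMatrix,
    attribute_importance,
    cut_clusters,
    example_profiles,
    fit,
    hierarchical_cluster,
    problem_profiles,
)

from oracles import average_linkage_merge


def _tml_frame(n=60, m=5, seed=0):
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(
        rng.standard_normal((n, m)), columns=[f"tml:t{j}" for j in range(m)]
    )
    return frame


class TestAttributeImportance:
    def test_informative_column_ranked_first_native(self):
        frame = _tml_frame(n=200, m=10, seed=1)
        y = frame["tml:t4"].to_numpy()
        model = fit(LearnerSpec("forest", {"n_estimators": 50}, seed=2), frame, y)
        ranking = attribute_importance(model, frame, y, method="native")
        assert ranking.rows.iloc[0]["source_task_id"] == "t4"
        assert ranking.method == "native"

    def test_percent_normalization_sums_to_100(self):
        frame = _tml_frame(n=100, m=4, seed=3)
        y = frame.sum(axis=1).to_numpy()
        model = fit(LearnerSpec("forest", {"n_estimators": 30}, seed=2), frame, y)
        ranking = attribute_importance(model, frame, y, method="native")
        assert ranking.rows["weight"].sum() == pytest.approx(100.0)
        assert (ranking.rows["weight"].diff().dropna() <= 1e-9).all()

    def test_knn_falls_back_to_permutation(self):
        frame = _tml_frame(n=60, m=3, seed=4)
        y = frame["tml:t0"].to_numpy()
        model = fit(LearnerSpec("knn", {"k": 3}), frame, y)
        ranking = attribute_importance(model, frame, y, method="native", seed=1)
        assert ranking.method == "permutation"
        assert ranking.rows.iloc[0]["source_task_id"] == "t0"

    def test_noise_column_permutation_importance_near_zero(self):
        rng = np.random.default_rng(5)
        frame = _tml_frame(n=150, m=3, seed=5)
        y = frame["tml:t0"].to_numpy() + 0.01 * rng.standard_normal(150)
        model = fit(LearnerSpec("knn", {"k": 5}), frame, y)
        ranking = attribute_importance(
            model, frame, y, method="permutation", normalization="raw",
            n_repeats=50, seed=2,
        )
        rows = ranking.rows.set_index("source_task_id")
        # t1/t2 are pure noise; their RMSE increase should be tiny vs t0's
        assert rows.loc["t1", "weight"] < 0.1 * rows.loc["t0", "weight"]
        assert rows.loc["t2", "weight"] < 0.1 * rows.loc["t0", "weight"]

    def test_duplicated_column_shares_importance(self):
        rng = np.random.default_rng(6)
        base = rng.standard_normal(200)
        frame = pd.DataFrame(
            {
                "tml:dup1": base,
                "tml:dup2": base,
                "tml:noise": rng.standard_normal(200),
            }
        )
        y = base + 0.05 * rng.standard_normal(200)
        model = fit(LearnerSpec("forest", {"n_estimators": 100}, seed=3), frame, y)
        ranking = attribute_importance(model, frame, y, method="native", normalization="raw")
        rows = ranking.rows.set_index("source_task_id")["weight"]
        # the two copies split the signal roughly evenly
        assert rows["dup1"] == pytest.approx(rows["dup2"], rel=0.5)
        assert rows["dup1"] + rows["dup2"] > 5 * rows["noise"]

    def test_top_k_truncates(self):
        frame = _tml_frame(n=50, m=6, seed=7)
        y = frame.sum(axis=1).to_numpy()
        model = fit(LearnerSpec("forest", {"n_estimators": 20}, seed=1), frame, y)
        ranking = attribute_importance(model, frame, y, top_k=3)
        assert len(ranking.rows) == 3
        assert list(ranking.rows["rank"]) == [1, 2, 3]

    def test_metadata_joined(self):
        frame = _tml_frame(n=50, m=2, seed=8)
        y = frame["tml:t0"].to_numpy()
        model = fit(LearnerSpec("forest", {"n_estimators": 20}, seed=1), frame, y)
        meta = {"t0": {"species": "H. sapiens"}, "t1": {"species": "E. coli"}}
        ranking = attribute_importance(model, frame, y, metadata=meta)
        assert "species" in ranking.rows.columns


class TestProfiles:
    def test_example_profile_shape(self, small_collection, small_registry, knn_spec):
        probe = small_collection["donkey"].X.iloc[:5]
        profiles = example_profiles(small_registry, knn_spec.digest, probe)
        assert profiles.matrix.shape == (5, 3)
        assert list(profiles.matrix.columns) == ["donkey", "kitten", "rabbit"]

    def test_problem_profiles_is_exact_transpose(
        self, small_collection, small_registry, knn_spec
    ):
        probe = small_collection["kitten"].X.iloc[:8]
        ex = example_profiles(small_registry, knn_spec.digest, probe)
        prob = problem_profiles(small_registry, knn_spec.digest, probe)
        pd.testing.assert_frame_equal(prob.matrix, ex.matrix.T)
        assert prob.axis == "problem_profiles"

    def test_duplicated_example_duplicates_profile_row(
        self, small_collection, small_registry, knn_spec
    ):
        probe = small_collection["donkey"].X.iloc[[0, 0]].set_axis(["a", "b"])
        profiles = example_profiles(small_registry, knn_spec.digest, probe)
        np.testing.assert_array_equal(
            profiles.matrix.iloc[0].to_numpy(), profiles.matrix.iloc[1].to_numpy()
        )


class TestHierarchicalCluster:
    def test_identical_rows_merge_first_at_zero(self):
        rng = np.random.default_rng(0)
        rows = rng.standard_normal((5, 4))
        rows[3] = rows[1]
        frame = pd.DataFrame(rows, index=list("abcde"))
        tree = hierarchical_cluster(frame, distance="euclidean", linkage="average")
        assert tree.heights[0] == pytest.approx(0.0)

    def test_three_collinear_points_average_linkage(self):
        # points at 0, 1, 3 on a line: close pair merges at 1, far point
        # joins at mean(2, 3) = 2.5
        frame = pd.DataFrame({"x": [0.0, 1.0, 3.0]}, index=["p0", "p1", "p2"])
        tree = hierarchical_cluster(frame, distance="euclidean", linkage="average")
        np.testing.assert_allclose(tree.heights, [1.0, 2.5])
        merges = average_linkage_merge(frame.to_numpy())
        assert merges[0][2] == pytest.approx(1.0)
        assert merges[1][2] == pytest.approx(2.5)

    def test_invariant_to_row_permutation(self):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame(rng.standard_normal((8, 5)), index=[f"r{i}" for i in range(8)])
        tree = hierarchical_cluster(frame)
        shuffled = frame.iloc[rng.permutation(8)]
        tree2 = hierarchical_cluster(shuffled)
        labels1 = cut_clusters(tree, k=3)
        labels2 = cut_clusters(tree2, k=3)
        partition1 = {frozenset(k for k, v in labels1.items() if v == c) for c in set(labels1.values())}
        partition2 = {frozenset(k for k, v in labels2.items() if v == c) for c in set(labels2.values())}
        assert partition1 == partition2

    def test_constant_row_rejected_for_correlation(self):
        frame = pd.DataFrame(
            [[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]], index=["ok", "flat"]
        )
        with pytest.raises(ConfigurationError, match="flat"):
            hierarchical_cluster(frame, distance="correlation")

    def test_ward_requires_euclidean(self):
        frame = pd.DataFrame(np.random.default_rng(2).standard_normal((4, 3)))
        with pytest.raises(ConfigurationError):
            hierarchical_cluster(frame, distance="correlation", linkage="ward")

    def test_newick_serializes_all_leaves(self):
        rng = np.random.default_rng(3)
        frame = pd.DataFrame(rng.standard_normal((6, 4)), index=[f"leaf{i}" for i in range(6)])
        newick = hierarchical_cluster(frame).to_newick()
        assert newick.endswith(";")
        for i in range(6):
            assert f"leaf{i}" in newick


class TestCutClusters:
    def _tree(self):
        rng = np.random.default_rng(4)
        frame = pd.DataFrame(rng.standard_normal((6, 3)), index=list("abcdef"))
        return hierarchical_cluster(frame, distance="euclidean")

    def test_k_equals_n_all_singletons(self):
        tree = self._tree()
        labels = cut_clusters(tree, k=6)
        assert len(set(labels.values())) == 6

    def test_k_one_single_cluster(self):
        labels = cut_clusters(self._tree(), k=1)
        assert set(labels.values()) == {1}

    def test_height_zero_groups_only_identical_pair(self):
        rows = np.random.default_rng(5).standard_normal((4, 3))
        rows[2] = rows[0]
        frame = pd.DataFrame(rows, index=list("wxyz"))
        tree = hierarchical_cluster(frame, distance="euclidean")
        labels = cut_clusters(tree, height=0.0)
        assert labels["w"] == labels["y"]
        assert len(set(labels.values())) == 3

    def test_both_k_and_height_rejected(self):
        with pytest.raises(ConfigurationError):
            cut_clusters(self._tree(), k=2, height=1.0)

    def test_labels_deterministic_by_leaf_order(self):
        labels = cut_clusters(self._tree(), k=3)
        assert labels["a"] == 1
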