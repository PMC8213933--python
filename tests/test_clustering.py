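import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform
from sklearn.base import clone

from caphier.clustering import (
    CapWardClustering,
    cosine_distance_matrix,
    cut_levels,
    labeling_from_levels,
    occupancy_split,
    split_percentages,
    ward_linkage,
)

from _oracles import scipy_tree_to_merges, ward_bruteforce_lw


class TestCosineDistance:
    def test_identical_rows_distance_zero(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0]])
        D = cosine_distance_matrix(X)
        assert D[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_rows_distance_one(self):
        D = cosine_distance_matrix(np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert D[0, 1] == pytest.approx(1.0)

    def test_hand_arithmetic_oracle(self):
        D = cosine_distance_matrix(np.array([[1.0, 0.0], [1.0, 1.0]]))
        assert D[0, 1] == pytest.approx(1 - 1 / np.sqrt(2), abs=1e-12)

    def test_zero_norm_row_rejected_with_provenance(self, small_vm):
        X = small_vm.values.copy()
        X[3] = 0.0
        vm = type(small_vm)(values=X, provenance=small_vm.provenance,
                            mask=small_vm.mask)
        with pytest.raises(ValueError, match="zero-norm"):
            cosine_distance_matrix(vm)

    def test_blocked_equals_unblocked(self, rng):
        X = rng.normal(size=(37, 8))
        np.testing.assert_allclose(cosine_distance_matrix(X, block_rows=5),
                                   cosine_distance_matrix(X, block_rows=1000))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(0.01, 100.0), st.integers(0, 9))
    def test_row_scale_invariance(self, c, row):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(10, 6))
        X2 = X.copy()
        X2[row] *= c
        np.testing.assert_allclose(cosine_distance_matrix(X2),
                                   cosine_distance_matrix(X), atol=1e-10)


class TestWardLinkage:
    def test_two_points_merge_at_their_distance(self):
        D = np.array([[0.0, 0.7], [0.7, 0.0]])
        tree = ward_linkage(D)
        assert tree.Z.shape == (1, 4)
        assert tree.heights[0] == pytest.approx(0.7)

    def test_collinear_points_merge_order(self):
        # points 0, 1, 10 on a line, Euclidean distances
        pts = np.array([[0.0], [1.0], [10.0]])
        D = squareform(pdist(pts))
        tree = ward_linkage(D)
        merges = scipy_tree_to_merges(tree.Z)
        assert merges[0][0] == frozenset({0, 1})
        assert merges[1][0] == frozenset({0, 1, 2})

    def test_heights_nondecreasing(self, small_tree):
        assert np.all(np.diff(small_tree.heights) >= -1e-12)

    def test_single_item_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            ward_linkage(np.zeros((1, 1)))

    def test_matches_lance_williams_bruteforce_on_cosine(self, rng):
        X = rng.normal(size=(9, 5))
        D = cosine_distance_matrix(X)
        tree = ward_linkage(D)
        got = scipy_tree_to_merges(tree.Z)
        expect = ward_bruteforce_lw(D)
        for (ma, ha), (mb, hb) in zip(got, expect):
            assert ma == mb
            assert ha == pytest.approx(hb, abs=1e-10)

    def test_matches_r_hclust_ward_d2_fixture(self):
        """Frozen cross-check against hclust(method='ward.D2') on the same
        cosine distance matrix (merge member-sets and heights)."""
        rng = np.random.default_rng(42)
        X = rng.normal(size=(8, 5))
        tree = ward_linkage(cosine_distance_matrix(X))
        r_heights = [0.08408345, 0.39913074, 0.41378471, 0.50454431,
                     1.43037118, 1.68394920, 2.13515518]
        np.testing.assert_allclose(tree.heights, r_heights, atol=1e-7)
        r_sets = [
            {6, 7}, {0, 4}, {1, 3}, {2, 5},
            {1, 2, 3, 5}, {0, 1, 2, 3, 4, 5}, set(range(8)),
        ]
        got = [set(m) for m, _ in scipy_tree_to_merges(tree.Z)]
        assert got == r_sets


class TestCutLevels:
    def test_fifty_eight_caps_from_levels_2_to_30(self, small_labeling):
        assert small_labeling.n_unique_caps == 58

    def test_single_level_two_caps(self, small_tree):
        lab = cut_levels(small_tree, 2, 2)
        assert lab.n_unique_caps == 2

    def test_unique_count_formula_on_random_tree(self, rng):
        X = rng.normal(size=(40, 6))
        tree = ward_linkage(cosine_distance_matrix(X))
        lab = cut_levels(tree, 2, 5)
        assert lab.n_unique_caps == 2 + 2 * (5 - 2)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.integers(2, 6), st.integers(0, 5), st.integers(0, 2 ** 31 - 1))
    def test_unique_count_formula_property(self, a, extra, seed):
        b = a + extra
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(b + 5, 4))
        lab = cut_levels(ward_linkage(cosine_distance_matrix(X)), a, b)
        assert lab.n_unique_caps == 2 + 2 * (b - a) + (a - 2)

    def test_partition_and_nestedness_every_level(self, small_labeling):
        lab = small_labeling
        for L in range(lab.level_min, lab.level_max + 1):
            labels = lab.labels_at(L)
            assert len(np.unique(labels)) == L
            if L > lab.level_min:
                # each level-L cluster sits inside exactly one level-(L-1) one
                prev = lab.labels_at(L - 1)
                for o in np.unique(labels):
                    assert len(np.unique(prev[labels == o])) == 1

    def test_parent_links_consistent_with_membership(self, small_labeling):
        lab = small_labeling
        for child, parent in lab.parent_of.items():
            cm = set(lab.members(child))
            pm = set(lab.members(parent))
            assert cm <= pm

    def test_level_max_above_n_errors(self, rng):
        X = rng.normal(size=(20, 4))
        tree = ward_linkage(cosine_distance_matrix(X))
        with pytest.raises(ValueError, match="level_max"):
            cut_levels(tree, 2, 30)

    def test_labeling_round_trips_through_level_arrays(self, small_labeling):
        back = labeling_from_levels(small_labeling.levels)
        assert back.n_unique_caps == small_labeling.n_unique_caps
        assert back.parent_of == small_labeling.parent_of
        for lab, m in small_labeling.unique_caps.items():
            np.testing.assert_array_equal(back.unique_caps[lab], m)


class TestOccupancySplit:
    def test_printed_branch_sizes_round_to_39_and_61_percent(self):
        pct = split_percentages([4658, 7272])
        assert list(pct) == [39, 61]

    def test_trivial_cut_each_cap_one_volume(self, rng):
        X = rng.normal(size=(12, 4))
        tree = ward_linkage(cosine_distance_matrix(X))
        lab = cut_levels(tree, 12, 12)
        df = occupancy_split(lab, 12)
        assert (df["count"] == 1).all()

    def test_noiseless_level2_recovers_macro_counts(self):
        from caphier import build_volume_matrix, generate_dataset
        from caphier.synthetic import effect_preset

        cfg = effect_preset(seed=3, n_subjects_per_group=2, n_volumes=40,
                            grid_shape=(12, 12, 10), n_networks=4,
                            noise_sd=0.0, group_effect_delta=0.0)
        ds = generate_dataset(cfg)
        vm = build_volume_matrix(ds)
        lab = cut_levels(ward_linkage(cosine_distance_matrix(vm)), 2, 2)
        macros = np.concatenate([ds.retained_state_labels(s)[:, 0]
                                 for s in range(ds.n_subjects)])
        df = occupancy_split(lab, 2)
        assert sorted(df["count"]) == sorted(np.bincount(macros).tolist())
        assert df["count"].sum() == vm.n_volumes


class TestEstimator:
    def test_fit_predict_labels_match_labeling(self, small_vm):
        est = CapWardClustering(level=2, level_max=10)
        labels = est.fit_predict(small_vm.values)
        assert set(labels) == {0, 1}
        np.testing.assert_array_equal(labels, est.labeling_.labels_at(2) - 1)

    def test_sklearn_params_round_trip_and_clone(self):
        est = CapWardClustering(level=3, level_max=8)
        params = est.get_params()
        assert params["level"] == 3
        cloned = clone(est)
        assert cloned.get_params() == params
        est.set_params(level=4)
        assert est.level == 4

    def test_level_max_validated_at_fit(self, rng):
        X = rng.normal(size=(10, 4))
        with pytest.raises(ValueError, match="level_max"):
            CapWardClustering(level_max=30).fit(X)
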