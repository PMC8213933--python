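import numpy as np
import pandas as pd
import pytest

from caphier.maps import compute_cap_zmaps
from caphier.rsn import (
    assign_voxels,
    bicluster_matrix,
    cap_rsn_mean_matrix,
    significant_fractions,
)


def _flat(vol, mask):
    return vol.ravel(order="F")[mask.ravel(order="F")]


class TestAssignVoxels:
    def test_highest_absolute_z_wins(self):
        mask = np.ones((1, 1, 1), dtype=bool)
        maps = np.array([2.0, -5.0, 1.0]).reshape(3, 1, 1, 1)
        atlas = assign_voxels(maps, mask)
        assert atlas.assignment[0] == 1

    def test_all_zero_voxel_unassigned(self):
        mask = np.ones((1, 1, 2), dtype=bool)
        maps = np.zeros((2, 1, 1, 2))
        maps[0, 0, 0, 0] = 1.0
        atlas = assign_voxels(maps, mask)
        assert atlas.assignment[0] == 0
        assert atlas.assignment[1] == -1

    def test_tie_breaks_to_lowest_index(self):
        mask = np.ones((1, 1, 1), dtype=bool)
        maps = np.array([3.0, 3.0]).reshape(2, 1, 1, 1)
        atlas = assign_voxels(maps, mask)
        assert atlas.assignment[0] == 0
        assert atlas.n_ties == 1

    def test_matches_generator_ownership(self, small_dataset):
        ds = small_dataset
        atlas = assign_voxels(ds.network_maps, ds.mask)
        own = _flat(ds.ownership, ds.mask)
        agree = (atlas.assignment == own).mean()
        assert agree >= 0.95

    def test_grid_mismatch_errors(self):
        with pytest.raises(ValueError, match="grid"):
            assign_voxels(np.zeros((2, 3, 3, 3)), np.ones((4, 4, 4), dtype=bool))


class TestMeanMatrix:
    def _zmap(self, z, undefined=None):
        from caphier.maps import CapZMap
        z = np.asarray(z, dtype=float)
        und = np.zeros(z.size, bool) if undefined is None else undefined
        return CapZMap("c", 10, z.copy(), np.ones(z.size), z, und)

    def _atlas(self, assignment, K=2):
        from caphier.rsn import RsnAtlas
        return RsnAtlas(np.asarray(assignment), [f"net-{k}" for k in range(K)], 0)

    def test_constant_z_gives_constant_entry(self):
        atlas = self._atlas([0, 0, 1, 1])
        mz = cap_rsn_mean_matrix({"c1": self._zmap([3, 3, 3, 3])}, atlas)
        assert mz.loc["net-0", "c1"] == pytest.approx(3.0)

    def test_balanced_signs_cancel(self):
        atlas = self._atlas([0] * 20, K=1)
        z = np.array([2.0] * 10 + [-2.0] * 10)
        mz = cap_rsn_mean_matrix({"c1": self._zmap(z)}, atlas)
        assert mz.loc["net-0", "c1"] == pytest.approx(0.0)

    def test_network_without_voxels_is_nan(self):
        atlas = self._atlas([0, 0, 0], K=2)
        mz = cap_rsn_mean_matrix({"c1": self._zmap([1, 2, 3])}, atlas)
        assert np.isnan(mz.loc["net-1", "c1"])

    def test_flagged_voxels_excluded(self):
        atlas = self._atlas([0, 0], K=1)
        und = np.array([False, True])
        mz = cap_rsn_mean_matrix({"c1": self._zmap([1.0, 99.0], und)}, atlas)
        assert mz.loc["net-0", "c1"] == pytest.approx(1.0)

    def test_sign_pattern_matches_amplitude_table(self):
        from caphier import (build_volume_matrix, cosine_distance_matrix,
                             cut_levels, generate_dataset, ward_linkage)
        from caphier.synthetic import effect_preset

        cfg = effect_preset(seed=17, n_subjects_per_group=2, n_volumes=40,
                            grid_shape=(12, 12, 10), n_networks=4,
                            noise_sd=0.0, group_effect_delta=0.0)
        ds = generate_dataset(cfg)
        vm = build_volume_matrix(ds)
        lab = cut_levels(ward_linkage(cosine_distance_matrix(vm)), 2, 2)
        zmaps = compute_cap_zmaps(vm, lab)
        atlas = assign_voxels(ds.network_maps, vm.mask)
        mz = cap_rsn_mean_matrix(zmaps, atlas)
        macros = np.concatenate([ds.retained_state_labels(s)[:, 0]
                                 for s in range(ds.n_subjects)])
        amp = cfg.resolved_amplitudes()
        P = cfg.substates_per_macro
        for o in (1, 2):
            c = lab.cap_label(2, o)
            macro = int(np.unique(macros[lab.members(c)])[0])
            for k in range(cfg.n_networks):
                assert np.sign(mz.loc[f"net-{k + 1:02d}", c]) == \
                       np.sign(amp[k, macro * P])


class TestBicluster:
    def test_identical_columns_adjacent(self, rng):
        M = rng.normal(size=(4, 5))
        M[:, 3] = M[:, 0]
        mz = pd.DataFrame(M)
        _, col_order = bicluster_matrix(mz)
        pos = list(col_order)
        assert abs(pos.index(0) - pos.index(3)) == 1

    def test_two_by_two_returns_permutations(self, rng):
        mz = pd.DataFrame(rng.normal(size=(2, 2)))
        ro, co = bicluster_matrix(mz)
        assert sorted(ro) == [0, 1] and sorted(co) == [0, 1]

    def test_column_permutation_equivariance(self, rng):
        """Permuting input columns yields the same clustering up to
        relabeling: the sets of columns merged at each tree node agree."""
        from caphier.clustering import cosine_distance_matrix, ward_linkage
        from _oracles import scipy_tree_to_merges

        M = pd.DataFrame(rng.normal(size=(5, 6)))
        perm = rng.permutation(6)
        Mp = M.iloc[:, perm]

        def merge_sets(df):
            tree = ward_linkage(cosine_distance_matrix(df.to_numpy().T))
            return {frozenset(df.columns[list(m)]) for m, _ in
                    scipy_tree_to_merges(tree.Z)}

        assert merge_sets(M) == merge_sets(Mp)

    def test_deterministic(self, rng):
        M = pd.DataFrame(rng.normal(size=(6, 7)))
        assert all(np.array_equal(a, b) for a, b in
                   zip(bicluster_matrix(M), bicluster_matrix(M)))

    def test_zero_row_moved_to_end(self, rng):
        M = pd.DataFrame(rng.normal(size=(4, 5)))
        M.iloc[2] = 0.0
        ro, _ = bicluster_matrix(M)
        assert ro[-1] == 2


class TestSignificantFractions:
    def _setup(self):
        from caphier.rsn import RsnAtlas
        assignment = np.array([0] * 100 + [1] * 50)
        atlas = RsnAtlas(assignment, ["net-a", "net-b"], 0)
        m = np.zeros(150, bool)
        m[:57] = True
        masks = {("02-01", "A>B"): m,
                 ("02-01", "B>A"): np.zeros(150, bool)}
        return atlas, masks

    def test_percentage_arithmetic_and_cell_format(self):
        atlas, masks = self._setup()
        out = significant_fractions(masks, atlas)
        assert out["pct"]["A>B"].loc["net-a", "02-01"] == pytest.approx(57.0)
        row = out["report"].iloc[0]
        assert "net-a, 57% (57/100)" in row["networks"]

    def test_counts_partition_total_significant(self):
        atlas, masks = self._setup()
        out = significant_fractions(masks, atlas)
        total = masks[("02-01", "A>B")].sum()
        by_net = out["counts"]["A>B"]["02-01"].sum()
        assert by_net == total

    def test_empty_masks_zero_pct_empty_decile(self):
        atlas, _ = self._setup()
        masks = {("02-01", "A>B"): np.zeros(150, bool),
                 ("02-01", "B>A"): np.zeros(150, bool)}
        out = significant_fractions(masks, atlas)
        for d in out["pct"]:
            assert (out["pct"][d].to_numpy() == 0).all()
            assert not out["decile_mask"][d].to_numpy().any()

    def test_injected_effect_column_max_on_affected_network(self):
        """A significant mask confined to network k puts the column maximum of
        the pct matrix at row k."""
        from caphier.rsn import RsnAtlas
        assignment = np.array([0] * 40 + [1] * 40 + [2] * 40)
        atlas = RsnAtlas(assignment, ["n0", "n1", "n2"], 0)
        m = np.zeros(120, bool)
        m[40:70] = True          # inside network 1 only
        masks = {("04-02", "B>A"): m}
        out = significant_fractions(masks, atlas)
        col = out["pct"]["B>A"]["04-02"]
        assert col.idxmax() == "n1"

    def test_connected_components_counted(self):
        from caphier.rsn import RsnAtlas
        mask3d = np.ones((4, 4, 4), dtype=bool)
        assignment = np.zeros(64, dtype=int)
        atlas = RsnAtlas(assignment, ["n0"], 0)
        sig = np.zeros((4, 4, 4), bool)
        sig[0, 0, 0] = True
        sig[3, 3, 3] = True      # two isolated voxels, 26-connectivity
        masks = {("02-01", "A>B"): sig.ravel(order="F")}
        out = significant_fractions(masks, atlas, mask3d=mask3d)
        assert out["report"]["clusters"].iloc[0] == 2
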