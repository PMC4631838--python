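import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from intmod.analysis import (
    contact_maps,
    exhaustiveness_check,
    jackknife,
    localization_density,
    map_cross_correlation,
    rmsd_matrix,
    rmsf,
    satisfaction_stats,
    segment_density,
    select_and_cluster,
    subunit_precision,
    weighted_rmsd,
)
from intmod.io_formats import VoxelMap
from intmod.representation import GMM
from intmod.sampling import Frame, ModelState, Trajectory
from intmod.xl_dataset import CrossLink, CrossLinkSet


class TestWeightedRmsd:
    def test_identical_states_zero(self, rng):
        x = rng.normal(size=(7, 3))
        assert weighted_rmsd(x, x, np.ones(7)) == 0.0

    def test_single_bead_displacement(self):
        assert weighted_rmsd([[0, 0, 0]], [[5.0, 0, 0]], [1]) == pytest.approx(5.0)

    def test_hand_arithmetic_with_sizes(self):
        a = np.array([[0, 0, 0], [0, 0, 0]], float)
        b = np.array([[2.0, 0, 0], [0, 0, 0]], float)
        # n = (1, 3), displacements (2, 0): sqrt(1*4 / 4) = 1.0
        assert weighted_rmsd(a, b, [1, 3]) == pytest.approx(1.0)

    def test_mismatched_beads_rejected(self):
        with pytest.raises(ValueError):
            weighted_rmsd(np.zeros((3, 3)), np.zeros((4, 3)), np.ones(3))

    def test_pseudo_metric_properties(self, rng):
        xs = rng.normal(scale=10, size=(6, 9, 3))
        w = rng.integers(1, 11, size=9).astype(float)
        D = rmsd_matrix(xs, w)
        np.testing.assert_allclose(D, D.T, atol=1e-12)
        assert np.allclose(np.diag(D), 0)
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert D[i, j] <= D[i, k] + D[k, j] + 1e-9

    def test_matrix_matches_brute_force(self, rng):
        xs = rng.normal(size=(5, 4, 3))
        w = rng.integers(1, 5, size=4).astype(float)
        D = rmsd_matrix(xs, w)
        for i in range(5):
            for j in range(5):
                assert D[i, j] == pytest.approx(weighted_rmsd(xs[i], xs[j], w), abs=1e-9)


def _fake_frames(model, states, scores):
    frames = []
    for st, s in zip(states, scores):
        frames.append(
            Frame(
                sweep=0,
                run=0,
                rot=st.rot.copy(),
                trans=st.trans.copy(),
                flex=st.flex.copy(),
                sigma=st.nuisances.sigma,
                psi=dict(st.nuisances.psi),
                score=float(s),
            )
        )
    return Trajectory(run=0, save_interval=1, frames=frames)


def _jittered_states(model, rng, n, amplitude, base=None):
    base = base or ModelState.reference(model)
    out = []
    for _ in range(n):
        st = base.copy()
        for bi in model.mobile_rigid:
            st.trans[bi] = st.trans[bi] + rng.normal(scale=amplitude, size=3)
        if model.n_flex:
            st.flex = st.flex + rng.normal(scale=amplitude, size=st.flex.shape)
        out.append(st)
    return out


class TestClustering:
    def test_identical_frames_single_cluster_zero_precision(self, toy):
        model = toy["model"]
        states = [ModelState.reference(model) for _ in range(12)]
        traj = _fake_frames(model, states, np.arange(12))
        ens = select_and_cluster(model, [traj], n_best=12, k=1)
        assert ens.n_clusters == 1
        assert ens.precision(0) == pytest.approx(0.0)

    def test_two_planted_conformations_perfectly_separated(self, toy, rng):
        model = toy["model"]
        near = _jittered_states(model, rng, 10, 0.5)
        far_base = ModelState.reference(model)
        for bi in model.mobile_rigid:
            far_base.trans[bi] = far_base.trans[bi] + np.array([120.0, 0, 0])
        far = _jittered_states(model, rng, 10, 0.5, base=far_base)
        traj = _fake_frames(model, near + far, np.arange(20))
        truth_labels = [0] * 10 + [1] * 10
        ens = select_and_cluster(model, [traj], n_best=20, k=2)
        assert adjusted_rand_score(truth_labels, ens.labels) == 1.0

    def test_center_matches_exhaustive_argmin(self, toy, rng):
        model = toy["model"]
        states = _jittered_states(model, rng, 15, 5.0)
        traj = _fake_frames(model, states, np.arange(15))
        ens = select_and_cluster(model, [traj], n_best=15, k=1)
        brute = int(np.argmin(ens.rmsd.sum(axis=1)))
        assert ens.center_index(0) == brute

    def test_assignment_invariant_to_frame_order(self, toy, rng):
        model = toy["model"]
        states = _jittered_states(model, rng, 8, 2.0) + _jittered_states(
            model, rng, 8, 2.0, base=None
        )
        scores = rng.normal(size=16)
        traj = _fake_frames(model, states, scores)
        ens1 = select_and_cluster(model, [traj], n_best=16, k=2)
        perm = rng.permutation(16)
        traj2 = _fake_frames(model, [states[i] for i in perm], scores[perm])
        ens2 = select_and_cluster(model, [traj2], n_best=16, k=2)
        # same partition content regardless of input order (frames are
        # re-sorted by score internally; compare cluster memberships by score id)
        def partition(ens):
            return {
                frozenset(np.round(ens.scores[ens.members(c)], 9)) for c in range(2)
            }

        assert partition(ens1) == partition(ens2)

    def test_k_larger_than_n_rejected(self, toy):
        model = toy["model"]
        states = [ModelState.reference(model)] * 3
        traj = _fake_frames(model, states, [1, 2, 3])
        with pytest.raises(ValueError):
            select_and_cluster(model, [traj], n_best=3, k=5)


class TestRmsfAndPrecision:
    def test_single_frame_cluster_rmsf_zero(self, toy):
        model = toy["model"]
        traj = _fake_frames(model, [ModelState.reference(model)], [0.0])
        ens = select_and_cluster(model, [traj], n_best=1, k=1)
        assert rmsf(ens, "C", 10) == 0.0

    def test_fixed_subunit_rmsf_zero(self, toy, rng):
        model = toy["model"]
        states = _jittered_states(model, rng, 6, 4.0)
        ens = select_and_cluster(model, [_fake_frames(model, states, np.arange(6))], 6, 1)
        assert rmsf(ens, "A", 30) == 0.0
        assert subunit_precision(ens, "A") == 0.0

    def test_three_frame_hand_computation(self, toy):
        model = toy["model"]
        ref = ModelState.reference(model)
        offsets = [0.0, 3.0, 6.0]
        states = []
        ci = [i for i, b in enumerate(model.rigid_bodies) if b.name == "C"][0]
        for off in offsets:
            st = ref.copy()
            st.trans[ci] = st.trans[ci] + np.array([off, 0, 0])
            states.append(st)
        ens = select_and_cluster(model, [_fake_frames(model, states, [1, 0, 2])], 3, 1)
        # center is the middle frame (offset 3); distances to it are 3, 0, 3
        assert ens.center_index(0) == np.argmin(ens.rmsd.sum(axis=1))
        expected = np.sqrt((9.0 + 0.0 + 9.0) / 3.0)
        assert rmsf(ens, "C", 10) == pytest.approx(expected)

    def test_unknown_selection_rejected(self, toy, rng):
        model = toy["model"]
        states = _jittered_states(model, rng, 3, 1.0)
        ens = select_and_cluster(model, [_fake_frames(model, states, [1, 2, 3])], 3, 1)
        with pytest.raises(KeyError):
            subunit_precision(ens, "Z")


class TestLocalizationDensity:
    def test_single_frame_binary_occupancy(self, toy):
        model = toy["model"]
        traj = _fake_frames(model, [ModelState.reference(model)], [0.0])
        ens = select_and_cluster(model, [traj], 1, 1)
        ld = localization_density(ens, "C", spacing=3.0)
        assert set(np.unique(ld.map.data)) <= {0.0, 1.0}

    def test_fixed_subunit_density_is_certain(self, toy, rng):
        model = toy["model"]
        states = _jittered_states(model, rng, 5, 3.0)
        ens = select_and_cluster(model, [_fake_frames(model, states, np.arange(5))], 5, 1)
        ld = localization_density(ens, "A", spacing=3.0)
        vals = np.unique(ld.map.data)
        assert set(vals) <= {0.0, 1.0}  # A never moves

    def test_two_disjoint_placements_average_to_half(self, toy):
        model = toy["model"]
        ref = ModelState.reference(model)
        moved = ref.copy()
        for bi in model.mobile_rigid:
            moved.trans[bi] = moved.trans[bi] + np.array([300.0, 0, 0])
        moved.flex = moved.flex + np.array([300.0, 0, 0])
        traj = _fake_frames(model, [ref, moved], [0, 1])
        ens = select_and_cluster(model, [traj], 2, 1)
        ld = localization_density(ens, "D", spacing=4.0)
        occupied = ld.map.data[ld.map.data > 0]
        np.testing.assert_allclose(occupied, 0.5)

    def test_gaussian_rasterization_smooth_and_mass_preserving(self, toy, rng):
        model = toy["model"]
        states = _jittered_states(model, rng, 3, 2.0)
        ens = select_and_cluster(model, [_fake_frames(model, states, np.arange(3))], 3, 1)
        ld = localization_density(ens, "C", spacing=3.0, rasterize="gaussian")
        # integrates to the subunit's residue count (per-frame average)
        total = ld.map.data.sum() * ld.map.voxel_volume
        n_res = model.bead_nres[model.bead_subunits == "C"].sum()
        assert total == pytest.approx(n_res, rel=0.05)

    def test_values_are_probabilities_and_average_of_frames(self, toy, rng):
        model = toy["model"]
        states = _jittered_states(model, rng, 4, 5.0)
        ens = select_and_cluster(model, [_fake_frames(model, states, np.arange(4))], 4, 1)
        from intmod.analysis import density_grid_for

        grid = density_grid_for(model, [ens.bead_coords.reshape(-1, 3)], spacing=4.0)
        whole = localization_density(ens, "C", grid=grid)
        assert whole.map.data.min() >= 0 and whole.map.data.max() <= 1
        per_frame = [
            localization_density(ens.bead_coords[[i]], "C", model=model, grid=grid).map.data
            for i in range(4)
        ]
        np.testing.assert_allclose(np.mean(per_frame, axis=0), whole.map.data, atol=1e-12)


class TestContacts:
    def test_threshold_rule_on_two_beads(self):
        # surface distance = center distance - r1 - r2
        assert (15.0 - 3.0 - 3.0) < 10.0
        assert (17.0 - 3.0 - 3.0) >= 10.0

    def test_frequencies_match_naive_double_loop(self, toy, rng):
        model = toy["model"]
        states = _jittered_states(model, rng, 5, 6.0)
        ens = select_and_cluster(model, [_fake_frames(model, states, np.arange(5))], 5, 1)
        maps = contact_maps(ens, cutoff=10.0)
        radii = model.bead_radii
        expect = np.zeros_like(maps["bead_frequency"])
        for coords in ens.bead_coords:
            for i in range(len(radii)):
                for j in range(len(radii)):
                    if i == j:
                        continue
                    d = np.linalg.norm(coords[i] - coords[j])
                    if d - radii[i] - radii[j] < 10.0:
                        expect[i, j] += 1
        np.testing.assert_allclose(maps["bead_frequency"], expect / 5.0, atol=1e-12)

    def test_domain_aggregation_uses_200_residue_blocks(self, toy, rng):
        model = toy["model"]
        states = _jittered_states(model, rng, 2, 1.0)
        ens = select_and_cluster(model, [_fake_frames(model, states, [0, 1])], 2, 1)
        maps = contact_maps(ens, domain_size=200)
        # toy subunits are 60 residues: one domain each except the split subunit
        assert len(maps["domains"]) == len({su for su in model.bead_subunits})


class TestSatisfaction:
    def test_colocated_endpoints_fully_satisfied(self, toy, truth_state):
        model = toy["model"]
        xs = CrossLinkSet.from_links([CrossLink("A", 1, "A", 2, xl_class="intra_module")])
        stats_ = satisfaction_stats(model, truth_state, xs, threshold=35.0)
        assert stats_["intra_module"]["satisfied_fraction"] == 1.0

    def test_beyond_threshold_violated(self, toy, truth_state):
        model, truth = toy["model"], toy["truth"]
        # pick a residue pair more than 35 Å apart in the ground truth
        pair = None
        for r1 in range(1, 41):
            for r2 in range(1, 41):
                if truth.distance("A", r1, "D", r2) > 40.0:
                    pair = (r1, r2)
                    break
            if pair:
                break
        xs = CrossLinkSet.from_links(
            [CrossLink("A", pair[0], "D", pair[1], xl_class="intra_module")]
        )
        stats_ = satisfaction_stats(model, truth_state, xs, threshold=35.0, surface_slack=False)
        assert stats_["intra_module"]["satisfied_fraction"] == 0.0

    def test_fractions_match_hand_count(self, toy, truth_state):
        model, xlset = toy["model"], toy["xlset"]
        links = xlset.links[:10]
        xs = CrossLinkSet.from_links(links)
        stats_ = satisfaction_stats(model, truth_state, xs, threshold=21.0, surface_slack=False)
        count = {"intra_module": [0, 0], "inter_module": [0, 0]}
        for xl in links:
            a = model.endpoint_coords(truth_state, [model.endpoint_of(xl.protein1, xl.residue1)])[0]
            b = model.endpoint_coords(truth_state, [model.endpoint_of(xl.protein2, xl.residue2)])[0]
            d = np.linalg.norm(a - b)
            count[xl.xl_class][0] += d <= 21.0
            count[xl.xl_class][1] += 1
        for cls, (sat, tot) in count.items():
            if tot:
                assert stats_[cls]["satisfied_fraction"] == pytest.approx(sat / tot)

    def test_monotone_in_threshold(self, toy, truth_state):
        model, xlset = toy["model"], toy["xlset"]
        fracs = [
            satisfaction_stats(model, truth_state, xlset, threshold=t)["all"]["satisfied_fraction"]
            for t in (5, 15, 25, 35, 60)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(fracs[:-1], fracs[1:]))


class TestExhaustivenessAndJackknife:
    def test_identical_halves_give_perfect_cc(self, toy, rng):
        model = toy["model"]
        states = _jittered_states(model, rng, 6, 1.0)
        t1 = _fake_frames(model, states, np.arange(6))
        t2 = _fake_frames(model, states, np.arange(6))
        report = exhaustiveness_check(model, [t1, t2], n_best_half=6)
        assert report["min_cc"] == pytest.approx(1.0)

    def test_jackknife_of_294_links_leaves_265(self):
        links = [CrossLink(f"P{i}", 1, f"Q{i}", 2) for i in range(294)]
        xs = CrossLinkSet.from_links(links)
        kept = jackknife(xs, 0.1, rng=np.random.default_rng(0))
        assert len(kept) == 265

    def test_jackknife_reproducible_with_seed(self, toy):
        a = jackknife(toy["xlset"], 0.1, rng=np.random.default_rng(7))
        b = jackknife(toy["xlset"], 0.1, rng=np.random.default_rng(7))
        assert {x.key for x in a} == {x.key for x in b}


class TestSegmentDensity:
    def _dumbbell(self, sep=40.0, sigma=6.0):
        g = GMM(
            np.array([1.0, 1.0]),
            np.array([[0.0, 0, 0], [sep, 0, 0]]),
            np.stack([sigma**2 * np.eye(3)] * 2),
        )
        return g.rasterize(spacing=2.0)

    def test_equal_masses_split_equal_volumes(self):
        vmap = self._dumbbell()
        parts = segment_density(vmap, None, {"M1": 1.0, "M2": 1.0}, threshold=1e-6)
        v1 = (parts["M1"].data > 0).sum()
        v2 = (parts["M2"].data > 0).sum()
        assert abs(v1 - v2) <= 1  # within one voxel of the target quota

    def test_zero_mass_module_gets_nothing(self):
        vmap = self._dumbbell()
        parts = segment_density(vmap, None, {"M1": 1.0, "M2": 0.0}, threshold=1e-6)
        assert (parts["M2"].data > 0).sum() == 0
        assert (parts["M1"].data > 0).sum() > 0

    def test_mass_ratio_2_1_splits_at_analytic_plane(self):
        """For a symmetric dumbbell along x, a 2:1 mass ratio must place the
        boundary at the 2/3 volume quantile of the x-sorted voxels."""
        vmap = self._dumbbell()
        parts = segment_density(vmap, None, {"Big": 2.0, "Small": 1.0}, threshold=1e-6)
        mask = vmap.data > 1e-6
        xs = vmap.voxel_centers().reshape(*vmap.data.shape, 3)[mask][:, 0]
        analytic_cut = np.quantile(xs, 2 / 3)
        big_x = vmap.voxel_centers().reshape(*vmap.data.shape, 3)[parts["Big"].data > 0][:, 0]
        small_x = vmap.voxel_centers().reshape(*vmap.data.shape, 3)[parts["Small"].data > 0][:, 0]
        assert abs(big_x.max() - analytic_cut) <= 2 * vmap.spacing
        assert small_x.min() >= big_x.max() - 1e-9

    def test_subtracts_fixed_component(self):
        vmap = self._dumbbell()
        fixed = GMM(np.array([1.0]), np.array([[0.0, 0, 0]]), 36 * np.eye(3)[None])
        parts = segment_density(
            vmap, fixed, {"M": 1.0}, fixed_mass=1.0, threshold=1e-6
        )
        # remaining density should concentrate in the second lobe
        xs = vmap.voxel_centers().reshape(*vmap.data.shape, 3)[parts["M"].data > 0][:, 0]
        assert np.median(xs) > 10.0


class TestMapCC:
    def test_identical_maps(self):
        v = VoxelMap(origin=np.zeros(3), spacing=1.0, data=np.random.default_rng(0).random((4, 4, 4)))
        assert map_cross_correlation(v, v) == pytest.approx(1.0)

    def test_mismatched_grids_rejected(self):
        a = VoxelMap(origin=np.zeros(3), spacing=1.0, data=np.ones((2, 2, 2)))
        b = VoxelMap(origin=np.zeros(3), spacing=1.0, data=np.ones((3, 2, 2)))
        with pytest.raises(ValueError):
            map_cross_correlation(a, b)
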