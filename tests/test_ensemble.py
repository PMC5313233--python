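"""Ensemble post-processing: RMSD, clustering, networks, classifiers, RMSF."""

import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pathcv.ensemble import (
    ClusterSet,
    ConformationPool,
    GeometricClassifierSpec,
    GeometricCriterion,
    LabelRule,
    build_network,
    classify_cluster,
    cluster_conformations,
    compute_rmsf,
    density_contours,
    mean_nearest_neighbor_distance,
    pairwise_rmsd,
)
from pathcv.errors import SpecError
from pathcv.langevin import run_langevin
from pathcv.restraints import Restraint
from pathcv.systems import ToySystemSpec
from pathcv.units import KB


def _blobs(rng, centers, n_each, scale=0.2, n_particles=6):
    """Well-separated blobs of conformations around template structures."""
    frames, labels = [], []
    templates = []
    for c in centers:
        t = rng.normal(size=(n_particles, 3)) * 2.0 + c
        templates.append(t)
    for k, t in enumerate(templates):
        for _ in range(n_each):
            frames.append(t + rng.normal(scale=scale, size=t.shape))
            labels.append(k)
    return np.array(frames), np.array(labels)


class TestPairwiseRMSD:
    def test_identical_frames_zero(self):
        frames = np.tile(np.arange(12.0).reshape(1, 4, 3), (3, 1, 1))
        np.testing.assert_allclose(pairwise_rmsd(frames), 0.0, atol=1e-10)

    def test_rigid_motion_removed_by_superposition(self, rng):
        frame = rng.normal(size=(5, 3))
        rot = Rotation.from_euler("zyx", [0.4, 1.0, -0.7]).as_matrix()
        moved = frame @ rot.T + np.array([3.0, -1.0, 8.0])
        m = pairwise_rmsd(np.stack([frame, moved]), superpose_frames=True)
        assert m[0, 1] < 1e-9
        raw = pairwise_rmsd(np.stack([frame, moved]), superpose_frames=False)
        assert raw[0, 1] > 1.0

    def test_three_particle_hand_example(self):
        """Without superposition the RMSD is √(Σd²/n) exactly."""
        a = np.zeros((3, 3))
        b = np.zeros((3, 3))
        b[0, 0] = 1.0  # one particle displaced by 1 Å
        m = pairwise_rmsd(np.stack([a, b]), superpose_frames=False)
        assert m[0, 1] == pytest.approx(np.sqrt(1.0 / 3.0))

    def test_against_scipy_alignment_oracle(self, rng):
        frames = rng.normal(size=(6, 7, 3)) * 3.0
        m = pairwise_rmsd(frames)
        for i, j in itertools.combinations(range(6), 2):
            a = frames[i] - frames[i].mean(axis=0)
            b = frames[j] - frames[j].mean(axis=0)
            rot, rssd = Rotation.align_vectors(a, b)
            expected = rssd / np.sqrt(7)
            assert m[i, j] == pytest.approx(expected, abs=1e-8)

    def test_symmetry_and_zero_diagonal(self, rng):
        frames = rng.normal(size=(5, 4, 3))
        m = pairwise_rmsd(frames)
        np.testing.assert_allclose(m, m.T)
        np.testing.assert_allclose(np.diag(m), 0.0)

    def test_single_frame_rejected(self):
        with pytest.raises(SpecError):
            pairwise_rmsd(np.zeros((1, 3, 3)))


class TestClustering:
    def test_planted_blobs_recovered_exactly(self, rng):
        frames, labels = _blobs(rng, centers=[0.0, 15.0, 40.0], n_each=12)
        cs = cluster_conformations(frames, threshold=3.0)
        assert cs.n_clusters == 3
        # partitions agree up to relabeling
        for k in range(3):
            members = np.flatnonzero(labels == k)
            assert len(set(cs.labels[members])) == 1
        cs.certify()

    def test_all_identical_single_cluster(self):
        frames = np.tile(np.arange(9.0).reshape(1, 3, 3), (8, 1, 1))
        cs = cluster_conformations(frames, threshold=3.0)
        assert cs.n_clusters == 1

    def test_zero_threshold_singletons(self, rng):
        frames = rng.normal(size=(6, 3, 3)) * 5
        cs = cluster_conformations(frames, threshold=0.0)
        assert cs.n_clusters == 6

    def test_permutation_invariance(self, rng):
        frames, _ = _blobs(rng, centers=[0.0, 12.0], n_each=10)
        cs1 = cluster_conformations(frames, threshold=3.0)
        perm = rng.permutation(len(frames))
        cs2 = cluster_conformations(frames[perm], threshold=3.0)
        parts1 = {frozenset(np.flatnonzero(cs1.labels == c))
                  for c in range(cs1.n_clusters)}
        parts2 = {frozenset(perm[np.flatnonzero(cs2.labels == c)])
                  for c in range(cs2.n_clusters)}
        assert parts1 == parts2

    def test_diameter_invariant_on_marginal_data(self, rng):
        """A continuum of frames forces nontrivial cuts; the certified
        diameter bound must still hold for every cluster."""
        drift = np.linspace(0, 10, 40)[:, None, None]
        frames = rng.normal(size=(1, 5, 3)) + drift * np.array([1.0, 0, 0])
        cs = cluster_conformations(frames, threshold=3.0)
        for c in range(cs.n_clusters):
            assert cs.diameter(c) <= 3.0 + 1e-9

    def test_empty_pool_rejected(self):
        with pytest.raises(SpecError):
            cluster_conformations(np.zeros((0, 3, 3)))

    def test_representatives_are_medoids(self, rng):
        frames, _ = _blobs(rng, centers=[0.0], n_each=9)
        cs = cluster_conformations(frames, threshold=5.0)
        m = cs.rmsd
        assert cs.representatives[0] == int(np.argmin(m.sum(axis=1)))


class TestNetwork:
    def _pool_with_two_groups(self, rng, gap):
        base = rng.normal(size=(4, 3)) * 2
        frames = np.concatenate([
            base[None] + rng.normal(scale=0.1, size=(5, 4, 3)),
            base[None] + np.array([gap, 0, 0.0]) + rng.normal(scale=0.1, size=(5, 4, 3)),
        ])
        return frames

    def test_edge_within_link_threshold(self, rng):
        frames = self._pool_with_two_groups(rng, gap=3.5)
        cs = cluster_conformations(frames, threshold=2.0, superpose_frames=False)
        g = build_network(cs, link_threshold=3.8, mode="single")
        assert cs.n_clusters == 2 and g.has_edge(0, 1)

    def test_no_edge_beyond_threshold(self, rng):
        frames = self._pool_with_two_groups(rng, gap=5.0)
        cs = cluster_conformations(frames, threshold=2.0, superpose_frames=False)
        g = build_network(cs, link_threshold=3.8, mode="single")
        assert not g.has_edge(0, 1)

    def test_adjacency_matches_member_pair_oracle(self, rng):
        frames, _ = _blobs(rng, centers=[0.0, 2.5, 6.0, 20.0], n_each=6,
                           scale=0.4)
        cs = cluster_conformations(frames, threshold=3.0)
        g = build_network(cs, link_threshold=3.8, mode="single")
        for a in range(cs.n_clusters):
            for b in range(a + 1, cs.n_clusters):
                ma, mb = cs.members(a), cs.members(b)
                d = min(cs.rmsd[i, j] for i in ma for j in mb)
                assert g.has_edge(a, b) == (d <= 3.8)
        assert not any(a == b for a, b in g.edges)


class TestClassifier:
    def _frames_with_distance(self, distances):
        frames = np.zeros((len(distances), 2, 3))
        frames[:, 1, 0] = distances
        return frames

    def test_fraction_above_half_true(self):
        frames = self._frames_with_distance([5.0] * 6 + [10.0] * 4)  # 60% < 8
        crit = GeometricCriterion(("atom-atom", 0, 1), 8.0, "lt", ("fraction", 0.5))
        spec = GeometricClassifierSpec((LabelRule("active", (crit,)),))
        assert classify_cluster(frames, spec) == "active"

    def test_exactly_half_is_false(self):
        """'More than 50%' is strict: an exact 50/50 split fails the criterion."""
        frames = self._frames_with_distance([5.0] * 5 + [10.0] * 5)
        crit = GeometricCriterion(("atom-atom", 0, 1), 8.0, "lt", ("fraction", 0.5))
        spec = GeometricClassifierSpec((LabelRule("active", (crit,)),))
        assert classify_cluster(frames, spec) == "other"

    def test_mean_com_distance_greater_than(self):
        frames = np.zeros((4, 3, 3))
        frames[:, 0, 0] = 8.0
        frames[:, 1, 0] = 9.0  # COM of {0,1} at 8.5 from particle 2
        crit = GeometricCriterion(("com-atom", (0, 1), 2), 8.0, "gt", ("mean",))
        spec = GeometricClassifierSpec((LabelRule("open", (crit,)),))
        assert classify_cluster(frames, spec) == "open"

    def test_first_satisfied_rule_wins(self):
        frames = self._frames_with_distance([5.0] * 10)
        crit = GeometricCriterion(("atom-atom", 0, 1), 8.0, "lt", ("fraction", 0.5))
        spec = GeometricClassifierSpec((
            LabelRule("first", (crit,)),
            LabelRule("second", (crit,)),
        ))
        assert classify_cluster(frames, spec) == "first"

    def test_missing_atom_named_in_error(self):
        frames = np.zeros((2, 2, 3))
        crit = GeometricCriterion(("atom-atom", 0, 7), 8.0)
        spec = GeometricClassifierSpec((LabelRule("x", (crit,)),))
        with pytest.raises(SpecError, match="7"):
            classify_cluster(frames, spec)

    def test_criterion_validation(self):
        with pytest.raises(SpecError):
            GeometricCriterion(("atom-atom", 0, 1), 0.0)
        with pytest.raises(SpecError):
            GeometricCriterion(("atom-atom", 0, 1), 8.0, aggregate=("fraction", 1.0))


class TestNearestCluster:
    def _cluster_set(self, rep_coords):
        n = len(rep_coords)
        frames = np.zeros((n, 1, 3))
        frames[:, 0, 0] = rep_coords
        rmsd = pairwise_rmsd(frames, superpose_frames=False)
        return ClusterSet(labels=np.arange(n), representatives=np.arange(n),
                          threshold=0.0, rmsd=rmsd)

    def test_single_pair(self):
        cs = self._cluster_set([0.0, 2.4])
        assert mean_nearest_neighbor_distance(cs, [0], [1]) == pytest.approx(2.4)

    def test_self_exclusion_within_same_set(self):
        cs = self._cluster_set([0.0, 1.0, 5.0])
        val = mean_nearest_neighbor_distance(cs, [0, 1, 2], [0, 1, 2])
        assert val == pytest.approx((1.0 + 1.0 + 4.0) / 3)

    def test_matches_exhaustive_enumeration(self, rng):
        coords = rng.uniform(0, 20, size=8)
        cs = self._cluster_set(coords)
        query, ref = [0, 2, 5], [1, 3, 4, 6, 7]
        expected = np.mean([min(abs(coords[q] - coords[r]) for r in ref)
                            for q in query])
        assert mean_nearest_neighbor_distance(cs, query, ref) == pytest.approx(expected)

    def test_empty_reference_rejected(self):
        cs = self._cluster_set([0.0, 1.0])
        with pytest.raises(SpecError):
            mean_nearest_neighbor_distance(cs, [0], [0])


class TestDensity:
    def test_single_bin_holds_all_mass(self):
        pts = np.tile([[0.5, 0.5]], (100, 1))
        dm = density_contours(pts, bins=10, ranges=((0, 1), (0, 1)))
        assert dm.density.max() == pytest.approx(1.0)
        assert dm.density.sum() == pytest.approx(1.0)

    def test_uniform_points_flat_within_noise(self, rng):
        pts = rng.uniform(size=(40000, 2))
        dm = density_contours(pts, bins=5, ranges=((0, 1), (0, 1)))
        expected = 1 / 25
        assert np.abs(dm.density - expected).max() < 5 * np.sqrt(expected / 40000)

    def test_bimodal_peaks_at_planted_modes(self, rng):
        pts = np.concatenate([
            rng.normal([-1, -1], 0.1, size=(500, 2)),
            rng.normal([1, 1], 0.1, size=(500, 2)),
        ])
        dm = density_contours(pts, bins=20, ranges=((-2, 2), (-2, 2)))
        peak = np.unravel_index(np.argmax(dm.density), dm.density.shape)
        xc = 0.5 * (dm.x_edges[peak[0]] + dm.x_edges[peak[0] + 1])
        assert abs(abs(xc) - 1.0) < 0.2

    def test_contour_levels_are_interval_multiples(self, rng):
        pts = rng.normal(size=(400, 2))
        dm = density_contours(pts, bins=8, contour_interval=0.005)
        np.testing.assert_allclose(np.diff(dm.contour_levels), 0.005)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(SpecError):
            density_contours(np.zeros((5, 2)), bins=4, ranges=((0, 0), (0, 1)))


class TestRMSF:
    def test_static_trajectory_zero(self):
        traj = np.tile(np.arange(12.0).reshape(1, 4, 3), (10, 1, 1))
        np.testing.assert_allclose(compute_rmsf(traj), 0.0, atol=1e-12)

    def test_translated_copies_zero_after_superposition(self, rng):
        frame = rng.normal(size=(5, 3))
        traj = np.stack([frame + np.array([t, 0, 0.0]) for t in range(8)])
        np.testing.assert_allclose(compute_rmsf(traj, superpose_frames=True),
                                   0.0, atol=1e-10)
        assert compute_rmsf(traj, superpose_frames=False).max() > 1.0

    def test_harmonic_equipartition(self):
        """An isotropically trapped particle has RMSF √(3 kBT/k) within 5%."""
        k, temp = 1.0, 300.0
        spec = ToySystemSpec("bead-chain",
                             {"n_beads": 3, "bond_stiffness": 1e-6, "bond_length": 1.0},
                             temperature=temp, friction=3.0, timestep=0.004, seed=8)
        restraints = [Restraint("harmonic", ("point", i, (4.0 * i, 0.0, 0.0)), 0.0, k)
                      for i in range(3)]
        x0 = np.zeros(9)
        x0[[0, 3, 6]] = [0.0, 4.0, 8.0]
        res = run_langevin(spec, restraints, n_steps=150_000, seed=8, x0=x0,
                           sample_stride=10)
        traj = res.positions.reshape(-1, 3, 3)[1000:]
        rmsf = compute_rmsf(traj, superpose_frames=False)
        np.testing.assert_allclose(rmsf, np.sqrt(3 * KB * temp / k), rtol=0.05)

    def test_too_short_trajectory_rejected(self):
        with pytest.raises(SpecError):
            compute_rmsf(np.zeros((1, 3, 3)))


def test_pool_validation(rng):
    with pytest.raises(SpecError):
        ConformationPool(rng.normal(size=(4, 5)))
    pool = ConformationPool(rng.normal(size=(4, 5, 3)))
    with pytest.raises(SpecError):
        pool.select([])
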