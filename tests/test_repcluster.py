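"""RMSD matrices and density-peak clustering."""

import numpy as np
import pytest

from halomode.errors import DegenerateInputError, GeometryError
from halomode.geometry import kabsch_superpose
from halomode.modeclass import FrameLabel, Mode
from halomode.repcluster import (DPCParams, RMSDMatrix, dpc_cluster,
                                 pairwise_rmsd_matrix, representative_frames)
from halomode.structio import SelectionSpec

from conftest import make_topology, make_trajectory


def _ca_topology(n):
    return make_topology([("CA", "C", "GLY", i + 1, "A") for i in range(n)])


def _blob_matrix(rng, sizes, centers, spread=0.05):
    """Euclidean distance matrix of 1-D blobs; returns (matrix, labels)."""
    points = np.concatenate([
        c + rng.normal(0, spread, size=s) for s, c in zip(sizes, centers)])
    labels = np.concatenate([[k] * s for k, s in enumerate(sizes)])
    D = np.abs(points[:, None] - points[None, :])
    return RMSDMatrix(values=D), labels, points


class TestPairwiseRmsdMatrix:
    def test_identical_frames_zero_matrix(self):
        frame = np.random.default_rng(1).normal(size=(5, 3))
        traj = make_trajectory([frame, frame, frame])
        m = pairwise_rmsd_matrix(traj, _ca_topology(5), SelectionSpec(indices=(0, 1, 2, 3, 4)))
        assert np.allclose(m.values, 0.0, atol=1e-9)

    def test_matches_per_pair_kabsch_oracle(self, rng):
        coords = rng.normal(0, 3, size=(5, 6, 3))
        traj = make_trajectory(coords)
        sel = SelectionSpec(indices=tuple(range(6)))
        m = pairwise_rmsd_matrix(traj, _ca_topology(6), sel)
        for i in range(5):
            for j in range(5):
                expected = 0.0 if i == j else kabsch_superpose(coords[i], coords[j]).rmsd
                assert m.values[i, j] == pytest.approx(expected, abs=1e-9)
        assert np.allclose(m.values, m.values.T, atol=1e-9)

    def test_too_few_atoms(self, rng):
        traj = make_trajectory(rng.normal(size=(2, 2, 3)))
        with pytest.raises(GeometryError):
            pairwise_rmsd_matrix(traj, _ca_topology(2), SelectionSpec(indices=(0, 1)))


class TestDpcCluster:
    def test_two_separated_blobs_recovered_exactly(self, rng):
        """Inter-blob distance >> intra: the partition must equal the
        ground-truth construction (checked per point against the nearest
        blob centre)."""
        m, truth, points = _blob_matrix(rng, sizes=(20, 20), centers=(0.0, 10.0))
        res = dpc_cluster(m, DPCParams(n_centers=2))
        assert len(res.centers) == 2
        # same partition up to cluster-id renaming
        mapping = {}
        for i, cid in enumerate(res.assignment):
            mapping.setdefault(cid, truth[i])
            assert mapping[cid] == truth[i]
        # agreement with a nearest-centroid assignment
        centroids = [points[res.centers[0]], points[res.centers[1]]]
        nearest = [int(np.argmin([abs(p - c) for c in centroids])) for p in points]
        remap = {res.assignment[res.centers[0]]: nearest[res.centers[0]],
                 res.assignment[res.centers[1]]: nearest[res.centers[1]]}
        assert [remap[c] for c in res.assignment] == nearest

    def test_single_blob_auto_one_center(self, rng):
        m, _, _ = _blob_matrix(rng, sizes=(30,), centers=(0.0,))
        res = dpc_cluster(m, DPCParams(n_centers="auto"))
        assert len(res.centers) == 1
        assert np.all(res.assignment == res.assignment[0])

    def test_auto_centers_find_two_blobs(self, rng):
        m, truth, _ = _blob_matrix(rng, sizes=(25, 15), centers=(0.0, 8.0))
        res = dpc_cluster(m, DPCParams(n_centers="auto"))
        assert len(res.centers) == 2

    def test_duplicate_points_tie_break_no_nan(self):
        D = np.zeros((4, 4))
        D[0, 3] = D[3, 0] = 5.0
        D[1, 3] = D[3, 1] = 5.0
        D[2, 3] = D[3, 2] = 5.0
        res = dpc_cluster(RMSDMatrix(values=D), DPCParams(d_c=1.0, n_centers=2))
        assert np.all(np.isfinite(res.rho))
        assert np.all(np.isfinite(res.delta))

    def test_global_density_max_gets_max_distance_delta(self, rng):
        m, _, _ = _blob_matrix(rng, sizes=(12, 5), centers=(0.0, 6.0))
        res = dpc_cluster(m, DPCParams(n_centers=2))
        top = int(np.argmax(res.rho))
        assert res.delta[top] == pytest.approx(m.values[top].max())

    def test_every_point_follows_its_nearest_higher(self, rng):
        m, _, _ = _blob_matrix(rng, sizes=(15, 15), centers=(0.0, 7.0))
        res = dpc_cluster(m, DPCParams(n_centers=2))
        for i in range(m.n):
            if i not in res.centers and res.nearest_higher[i] >= 0:
                assert res.assignment[i] == res.assignment[res.nearest_higher[i]]

    def test_relabeling_invariance(self, rng):
        m, _, points = _blob_matrix(rng, sizes=(10, 10), centers=(0.0, 9.0))
        perm = rng.permutation(m.n)
        mp = RMSDMatrix(values=m.values[np.ix_(perm, perm)])
        a = dpc_cluster(m, DPCParams(n_centers=2)).assignment
        b = dpc_cluster(mp, DPCParams(n_centers=2)).assignment
        # partitions agree up to renaming after undoing the permutation
        b_unperm = np.empty_like(b)
        b_unperm[perm] = b
        pairs = {}
        for x, y in zip(a, b_unperm):
            pairs.setdefault(x, y)
            assert pairs[x] == y

    def test_gamma_ranking_scale_invariant(self, rng):
        m, _, _ = _blob_matrix(rng, sizes=(10, 10), centers=(0.0, 9.0))
        r1 = dpc_cluster(m, DPCParams(d_c=0.5, n_centers=2))
        m2 = RMSDMatrix(values=3.0 * m.values)
        r2 = dpc_cluster(m2, DPCParams(d_c=1.5, n_centers=2))
        assert np.argsort(-r1.gamma).tolist() == np.argsort(-r2.gamma).tolist()

    def test_all_identical_points_degenerate(self):
        with pytest.raises(DegenerateInputError):
            dpc_cluster(RMSDMatrix(values=np.zeros((5, 5))))


class TestRepresentativeFrames:
    def _make_traj(self, rng, n_big=30, n_small=5):
        """Mode-1 frames form a 30-frame blob plus a 5-frame outlier blob;
        mode-2 frames are identical copies."""
        base_a = rng.normal(0, 3, size=(6, 3))
        base_b = base_a + np.array([8.0, 0, 0])
        frames, labels = [], []
        for k in range(n_big):
            frames.append(base_a + rng.normal(0, 0.02, size=(6, 3)))
            labels.append(FrameLabel(len(frames) - 1, Mode.MODE1, False, 3, 4))
        for k in range(n_small):
            frames.append(base_b + rng.normal(0, 0.02, size=(6, 3)))
            labels.append(FrameLabel(len(frames) - 1, Mode.MODE1, False, 3, 4))
        for k in range(3):
            frames.append(base_a)
            labels.append(FrameLabel(len(frames) - 1, Mode.MODE2, False, 3, 4))
        return make_trajectory(frames), labels

    def test_center_comes_from_dominant_blob(self, rng):
        traj, labels = self._make_traj(rng)
        res = representative_frames(traj, _ca_topology(6), labels,
                                    SelectionSpec(indices=tuple(range(6))),
                                    DPCParams(n_centers=2))
        assert res.frames[Mode.MODE1] < 30  # from the 30-frame blob

    def test_identical_mode_frames_yield_lowest_index(self, rng):
        traj, labels = self._make_traj(rng)
        res = representative_frames(traj, _ca_topology(6), labels,
                                    SelectionSpec(indices=tuple(range(6))),
                                    DPCParams(n_centers=1))
        assert res.frames[Mode.MODE2] == 35  # first of the identical copies

    def test_missing_mode_reports_error_others_survive(self, rng):
        traj, labels = self._make_traj(rng)
        single = [l for l in labels if l.mode is Mode.MODE1][:1]
        labels2 = [l for l in labels if l.mode is Mode.MODE2] + single
        res = representative_frames(traj, _ca_topology(6), labels2,
                                    SelectionSpec(indices=tuple(range(6))),
                                    DPCParams(n_centers=1))
        assert Mode.MODE1 in res.errors
        assert Mode.MODE2 in res.frames
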