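"""Shortest-path distance completion, classical MDS, hull rescaling and
telomere distance matrices."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import telohic as th


def floyd_warshall_oracle(W):
    """Brute-force all-pairs shortest paths; W[i,j] = edge weight, inf if absent."""
    n = W.shape[0]
    D = W.copy()
    np.fill_diagonal(D, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def pairwise(X):
    d = X[:, None, :] - X[None, :, :]
    return np.sqrt((d ** 2).sum(-1))


class TestContactToDistance:
    def test_single_edge_inverse_frequency(self):
        D = th.contact_to_distance(np.array([[0.0, 0.5], [0.5, 0.0]]))
        assert D[0, 1] == pytest.approx(2.0)

    def test_indirect_path_beats_direct_edge(self):
        A = np.array([[0.0, 0.1, 0.05], [0.1, 0.0, 1.0], [0.05, 1.0, 0.0]])
        D = th.contact_to_distance(A)
        assert D[0, 2] == pytest.approx(11.0)  # via middle: 10 + 1 < 20

    def test_matches_floyd_warshall_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = rng.integers(3, 13)
            A = rng.uniform(0, 1, (n, n))
            A = 0.5 * (A + A.T)
            A[A < 0.3] = 0.0  # sparsify
            np.fill_diagonal(A, 0)
            W = np.where(A > 0, 1.0 / np.where(A > 0, A, 1), np.inf)
            from scipy.sparse.csgraph import connected_components
            import scipy.sparse

            ncomp, _ = connected_components(scipy.sparse.csr_matrix((A > 0) * 1.0))
            if ncomp > 1:
                with pytest.raises(ValueError, match="disconnected"):
                    th.contact_to_distance(A)
                continue
            D = th.contact_to_distance(A)
            # identical path sums up to float summation order
            np.testing.assert_allclose(D, floyd_warshall_oracle(W), rtol=1e-12, atol=0)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(1)
        A = rng.uniform(0.1, 1, (8, 8))
        A = 0.5 * (A + A.T)
        np.fill_diagonal(A, 0)
        D = th.contact_to_distance(A)
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    assert D[i, k] <= D[i, j] + D[j, k] + 1e-12

    def test_disconnected_graph_reported(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 1.0
        A[2, 3] = A[3, 2] = 1.0
        with pytest.raises(ValueError, match="2 components"):
            th.contact_to_distance(A)


class TestEmbed3D:
    def test_recovers_random_3d_configuration(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 3))
        D = pairwise(X)
        Y = th.embed_3d(D)
        np.testing.assert_allclose(pairwise(Y), D, atol=1e-6)

    def test_unit_square_planar_embedding(self):
        D = np.array(
            [
                [0, 1, np.sqrt(2), 1],
                [1, 0, 1, np.sqrt(2)],
                [np.sqrt(2), 1, 0, 1],
                [1, np.sqrt(2), 1, 0],
            ]
        )
        Y = th.embed_3d(D)
        np.testing.assert_allclose(pairwise(Y), D, atol=1e-9)
        assert np.abs(Y[:, 2]).max() < 1e-9  # third coordinate vanishes

    def test_duplicate_points_remain_coincident(self):
        X = np.array([[0, 0, 0], [0, 0, 0], [1, 0, 0], [0, 2, 0.5]], dtype=float)
        Y = th.embed_3d(pairwise(X))
        assert np.linalg.norm(Y[0] - Y[1]) < 1e-9

    def test_low_rank_input_warns(self):
        # two points: at most 1 positive eigenvalue
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.warns(UserWarning, match="positive eigenvalues"):
            Y = th.embed_3d(D)
        assert Y.shape == (2, 3)

    def test_invariant_to_relabeling(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(12, 3))
        D = pairwise(X)
        perm = rng.permutation(12)
        Y1 = th.embed_3d(D)
        Y2 = th.embed_3d(D[np.ix_(perm, perm)])
        np.testing.assert_allclose(pairwise(Y2), pairwise(Y1)[np.ix_(perm, perm)], atol=1e-8)


class TestRoundTrip:
    def test_noiseless_structure_roundtrip_within_1pct(self, genome16, bead_bins16):
        """Planted structure -> expected map f=c/d -> shortest path + MDS
        reproduces every pairwise distance (direct edges dominate because
        Euclidean distances obey the triangle inequality)."""
        _, bins = bead_bins16
        s = th.simulate_structure(genome16, th.NucleusConfig(mode="uniform", seed=13))
        F = th.expected_contact_map(s)
        D = th.contact_to_distance(F)
        Y = th.embed_3d(D)
        Dtrue = s.pairwise_distances()
        iu = np.triu_indices(s.n_beads, 1)
        rel = np.abs(pairwise(Y)[iu] - Dtrue[iu]) / Dtrue[iu]
        assert rel.max() < 0.01

    def test_reconstruct_structure_labels(self, genome16, bead_bins16):
        _, bins = bead_bins16
        s = th.simulate_structure(genome16, th.NucleusConfig(mode="uniform", seed=14))
        M = th.ContactMatrix(th.expected_contact_map(s), bins, stage="normalized")
        rec = th.reconstruct_structure(M, genome16)
        assert rec.n_beads == s.n_beads
        assert (rec.labels == "centromere").sum() == 16
        assert (rec.labels == "rdna").sum() >= 1
        assert (rec.labels == "subtelomere").sum() == 32


class TestRescale:
    def _structure(self, coords):
        n = len(coords)
        return th.Structure3D(["c"] * n, range(n), coords, ["body"] * n)

    def _random_structures(self, seed=0):
        rng = np.random.default_rng(seed)
        return self._structure(rng.normal(size=(30, 3))), self._structure(
            2.5 * rng.normal(size=(25, 3))
        )

    def test_step1_equalizes_hull_volumes(self):
        from scipy.spatial import ConvexHull

        s_a, s_b = self._random_structures()
        diam = 1.5
        a, b = th.rescale_structures(s_a, s_b, diam, diam)
        va, vb = ConvexHull(a.coords).volume, ConvexHull(b.coords).volume
        assert abs(va - vb) / va < 1e-9

    def test_volume_matches_nuclear_sphere(self):
        from scipy.spatial import ConvexHull

        s_a, s_b = self._random_structures(1)
        a, b = th.rescale_structures(s_a, s_b, 1.5, 1.7)
        # coordinates in 10-nm units: sphere volumes in those units
        v_sph = lambda d_um: 4 / 3 * np.pi * (d_um / 2 * 100) ** 3
        assert ConvexHull(a.coords).volume == pytest.approx(v_sph(1.5), rel=1e-9)
        assert ConvexHull(b.coords).volume == pytest.approx(v_sph(1.7), rel=1e-9)

    def test_prescaling_invariance(self):
        """Scaling an input by 2 changes nothing after rescaling."""
        s_a, s_b = self._random_structures(2)
        a1, _ = th.rescale_structures(s_a, s_b, 1.5, 1.7)
        s_a2 = self._structure(2.0 * s_a.coords)
        a2, _ = th.rescale_structures(s_a2, s_b, 1.5, 1.7)
        np.testing.assert_allclose(pairwise(a1.coords), pairwise(a2.coords), rtol=1e-9)

    def test_commutes_with_rotation(self):
        s_a, s_b = self._random_structures(3)
        R = Rotation.from_euler("xyz", [0.3, -1.0, 2.0]).as_matrix()
        s_ar = self._structure(s_a.coords @ R.T)
        a1, b1 = th.rescale_structures(s_a, s_b, 1.5, 1.7)
        a2, b2 = th.rescale_structures(s_ar, s_b, 1.5, 1.7)
        np.testing.assert_allclose(pairwise(a2.coords), pairwise(a1.coords), rtol=1e-7)

    def test_degenerate_hull_rejected(self):
        flat = np.zeros((10, 3))
        flat[:, 0] = np.arange(10)
        s_a = self._structure(flat)
        s_b, _ = self._random_structures(4)
        with pytest.raises(Exception):
            th.rescale_structures(s_a, s_b, 1.5, 1.7)


class TestTelomereDistances:
    def test_32x32_for_full_karyotype(self, genome16):
        s = th.simulate_structure(genome16, th.NucleusConfig(mode="G1_rabl", seed=3))
        T = th.telomere_distance_matrix(s, genome16)
        assert T.matrix.shape == (32, 32)
        assert np.array_equal(T.matrix, T.matrix.T)
        assert np.diagonal(T.matrix).max() == 0

    def test_ordering_by_arm_length(self, genome16):
        s = th.simulate_structure(genome16, th.NucleusConfig(mode="G1_rabl", seed=3))
        T = th.telomere_distance_matrix(s, genome16)
        arm_lengths = [t[2] for t in T.telomeres]
        assert arm_lengths == sorted(arm_lengths)

    def test_missing_chromosome_dropped_with_warning(self, genome16):
        s = th.simulate_structure(genome16, th.NucleusConfig(mode="G1_rabl", seed=3))
        keep = s.chrom != "chrIV"
        sub = th.Structure3D(s.chrom[keep], s.bead[keep], s.coords[keep], s.labels[keep])
        with pytest.warns(UserWarning, match="chrIV"):
            T = th.telomere_distance_matrix(sub, genome16)
        assert T.matrix.shape == (30, 30)

    def test_g0_median_below_g1_from_full_pipeline(self, genome16, matched_runs):
        recs = {}
        for mode in ("G0_hypercluster", "G1_rabl"):
            recs[mode] = th.reconstruct_structure(matched_runs[mode]["normalized"], genome16)
        g0, g1 = th.rescale_structures(recs["G0_hypercluster"], recs["G1_rabl"], 1.5, 1.7)
        m0 = th.telomere_distance_matrix(g0, genome16).median_distance()
        m1 = th.telomere_distance_matrix(g1, genome16).median_distance()
        assert m0 < m1
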