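"""Synthetic-data generators: planted structures, sampled contact maps,
read pairs and rendered nucleus images."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist
from scipy.stats import chisquare

import telohic as th
from telohic.synth import BOND_LENGTH


@pytest.fixture(scope="module")
def g0_structure(genome16):
    return th.simulate_structure(genome16, th.NucleusConfig(mode="G0_hypercluster", seed=5))


@pytest.fixture(scope="module")
def g1_structure(genome16):
    return th.simulate_structure(genome16, th.NucleusConfig(mode="G1_rabl", seed=5))


class TestSimulateStructure:
    def test_g0_terminal_beads_clustered(self, g0_structure):
        cfg = th.NucleusConfig(mode="G0_hypercluster", seed=5)
        term = [i for a, b in g0_structure.terminal_indices().values() for i in (a, b)]
        assert len(term) == 32
        assert pdist(g0_structure.coords[term]).max() <= 2 * cfg.cluster_radius + 1e-9

    def test_g0_terminal_centroid_in_inner_zone(self, g0_structure):
        """Hypercluster centroid lies in the innermost equal-area zone of
        the focal plane through the nucleus center."""
        cfg = th.NucleusConfig(mode="G0_hypercluster", seed=5)
        term = [i for a, b in g0_structure.terminal_indices().values() for i in (a, b)]
        centroid = g0_structure.coords[term].mean(axis=0)
        r_xy = np.hypot(centroid[0], centroid[1])
        assert r_xy < cfg.radius * np.sqrt(1 / 3)

    def test_g1_terminal_beads_at_envelope(self, g1_structure):
        cfg = th.NucleusConfig(mode="G1_rabl", seed=5)
        term = [i for a, b in g1_structure.terminal_indices().values() for i in (a, b)]
        radii = np.linalg.norm(g1_structure.coords[term], axis=1)
        assert (radii >= cfg.radius - cfg.tether_tolerance - 1e-9).all()

    def test_g1_centromeres_tethered_near_spb(self, g1_structure):
        cfg = th.NucleusConfig(mode="G1_rabl", seed=5)
        cen = g1_structure.coords[g1_structure.labels == "centromere"]
        spb_point = np.array(cfg.spb_direction) * (cfg.radius - 2 * cfg.tether_tolerance)
        assert np.linalg.norm(cen - spb_point, axis=1).max() <= cfg.tether_tolerance + 1e-9

    @pytest.mark.parametrize("mode", ["G0_hypercluster", "G1_rabl", "uniform"])
    def test_chain_and_confinement_invariants(self, genome16, mode):
        cfg = th.NucleusConfig(mode=mode, seed=2)
        s = th.simulate_structure(genome16, cfg)
        assert np.linalg.norm(s.coords, axis=1).max() <= cfg.radius + 1e-9
        for c in s.chrom_order():
            idx = s.beads_of(c)
            steps = np.linalg.norm(np.diff(s.coords[idx], axis=0), axis=1)
            assert steps.max() <= BOND_LENGTH * 1.01
            assert steps.min() > 0

    def test_rdna_beads_in_peripheral_sector(self, g0_structure, g1_structure):
        for s in (g0_structure, g1_structure):
            rdna = s.coords[s.labels == "rdna"]
            assert len(rdna) >= 1
            radii = np.linalg.norm(rdna, axis=1)
            assert (radii >= 0.5).all()  # peripheral half, nucleus radius 1 um
            # opposite the SPB (+z by default)
            assert (rdna[:, 2] < 0).all()

    def test_deterministic_given_seed(self, genome16):
        cfg = th.NucleusConfig(mode="G1_rabl", seed=9)
        s1 = th.simulate_structure(genome16, cfg)
        s2 = th.simulate_structure(genome16, cfg)
        assert np.array_equal(s1.coords, s2.coords)

    def test_infeasible_constraints_diagnosed(self, genome16):
        cfg = th.NucleusConfig(mode="G1_rabl", seed=0, tether_tolerance=0.001)
        with pytest.raises(RuntimeError, match="constraints"):
            th.simulate_structure(genome16, cfg, bond_length=0.01, max_tries=5)

    def test_structure_tsv_roundtrip(self, tmp_path, g0_structure):
        p = tmp_path / "s.tsv"
        g0_structure.write_tsv(p)
        s2 = th.Structure3D.read_tsv(p)
        assert s2.units == g0_structure.units
        np.testing.assert_allclose(s2.coords, g0_structure.coords, atol=1e-9)
        assert list(s2.labels) == list(g0_structure.labels)


class TestContactSampling:
    def _toy_structure(self, coords):
        n = len(coords)
        g = th.build_toy_genome(1, [(n * 10_000, n * 10_000)])
        return th.Structure3D(["chr1"] * n, range(n), np.asarray(coords, float), ["body"] * n)

    def _bins_for(self, n):
        g = th.build_toy_genome(1, [(n * 10_000, n * 10_000)])
        fm = th.uniform_fragment_map(g, 20_000)
        return th.bin_fragments(fm, 1)

    def test_expected_ratio_inverse_distance(self):
        """Counts for pairs at distance 1 vs 2 approach the 2:1 ratio of the
        sampling model (within 3 sigma at n = 1e6)."""
        s = self._toy_structure([[0, 0, 0], [1, 0, 0], [-2, 0, 0]])
        M = th.structure_to_contact_map(s, self._bins_for(3), n_contacts=1_000_000, seed=0)
        n12, n13 = M.matrix[0, 1], M.matrix[0, 2]
        # p12 = (1/1)/(1+1/2+1/3), var per multinomial cell
        ps = np.array([1.0, 0.5, 1 / 3.0])
        ps /= ps.sum()
        expected = 1e6 * ps
        sd = np.sqrt(1e6 * ps * (1 - ps))
        assert abs(n12 - expected[0]) < 3 * sd[0]
        assert abs(n13 - expected[1]) < 3 * sd[1]

    def test_sampling_matches_inverse_distance_chisquare(self):
        """Empirical pair frequencies on a 10-bead toy pass a chi-square
        goodness-of-fit against c0/d at n = 1e6."""
        rng = np.random.default_rng(8)
        coords = rng.normal(size=(10, 3))
        s = self._toy_structure(coords)
        M = th.structure_to_contact_map(s, self._bins_for(10), n_contacts=1_000_000, seed=1)
        W = th.expected_contact_map(s)
        iu = np.triu_indices(10, 1)
        p = W[iu] / W[iu].sum()
        stat, pval = chisquare(M.matrix[iu], 1_000_000 * p)
        assert pval > 1e-3

    def test_symmetry_and_zero_contacts(self):
        s = self._toy_structure([[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        M = th.structure_to_contact_map(s, self._bins_for(3), n_contacts=1000, seed=3)
        assert np.array_equal(M.matrix, M.matrix.T)
        M0 = th.structure_to_contact_map(s, self._bins_for(3), n_contacts=0, seed=3)
        assert M0.matrix.sum() == 0

    def test_degenerate_structure_rejected(self):
        s = self._toy_structure([[0, 0, 0], [0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValueError, match="degenerate|coincident"):
            th.structure_to_contact_map(s, self._bins_for(3), n_contacts=10, seed=0)

    def test_deterministic_given_seed(self):
        s = self._toy_structure([[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        M1 = th.structure_to_contact_map(s, self._bins_for(3), n_contacts=5000, seed=7)
        M2 = th.structure_to_contact_map(s, self._bins_for(3), n_contacts=5000, seed=7)
        assert np.array_equal(M1.matrix, M2.matrix)


@pytest.fixture(scope="module")
def setup(genome2):
    fm = th.uniform_fragment_map(genome2, 20_000)
    bins = th.bin_fragments(fm, 1)
    s = th.simulate_structure(genome2, th.NucleusConfig(mode="uniform", seed=1))
    probs = th.ContactMatrix(th.expected_contact_map(s), bins, stage="normalized")
    return fm, bins, probs


class TestReadPairSimulation:
    def test_clean_round_trip_exact(self, setup):
        fm, bins, probs = setup
        pairs, truth = th.simulate_read_pairs(probs, fm, n_pairs=2000, seed=4)
        kept, _ = th.preprocess_pairs(pairs)
        M, rejected = th.build_contact_matrix(kept, fm, bins)
        assert rejected == 0
        assert np.array_equal(M.matrix, truth["pair_counts"])

    def test_duplicate_count_binomial(self, setup):
        fm, _, probs = setup
        n, q = 10_000, 0.2
        pairs, truth = th.simulate_read_pairs(probs, fm, n_pairs=n, dup_fraction=q, seed=5)
        _, stats = th.preprocess_pairs(pairs)
        tol = 3 * np.sqrt(n * q * (1 - q))
        assert abs(truth["n_duplicates"] - n * q) < tol
        assert stats.n_duplicates_collapsed == truth["n_duplicates"]

    def test_lowq_pairs_filtered(self, setup):
        fm, bins, probs = setup
        pairs, truth = th.simulate_read_pairs(probs, fm, n_pairs=5000, lowq_fraction=0.3, seed=6)
        kept, stats = th.preprocess_pairs(pairs)
        assert stats.n_lowq_removed == truth["n_lowq_pairs"]
        M, _ = th.build_contact_matrix(kept, fm, bins)
        assert np.array_equal(M.matrix, truth["clean_pair_counts"])

    def test_invalid_fractions(self, setup):
        fm, _, probs = setup
        with pytest.raises(ValueError):
            th.simulate_read_pairs(probs, fm, n_pairs=10, dup_fraction=1.5)

    def test_deterministic_given_seed(self, setup):
        fm, _, probs = setup
        p1, _ = th.simulate_read_pairs(probs, fm, n_pairs=500, dup_fraction=0.1, seed=8)
        p2, _ = th.simulate_read_pairs(probs, fm, n_pairs=500, dup_fraction=0.1, seed=8)
        assert p1.equals(p2)

    def test_pairs_tsv_roundtrip(self, setup, tmp_path):
        from telohic.hic import read_pairs, write_pairs

        fm, _, probs = setup
        pairs, _ = th.simulate_read_pairs(probs, fm, n_pairs=200, seed=9)
        p = tmp_path / "pairs.tsv"
        write_pairs(pairs, p)
        back = read_pairs(p)
        assert back.equals(pairs)


class TestRenderImage:
    def test_noise_free_intensity_integral(self, nucleus_image_geometry):
        spec = th.FociSpec([th.GaussianFocus((1.4, 1.5, 1.6), 5000.0)], background=0.0)
        img, _ = th.render_nucleus_image(spec, noise=False, **nucleus_image_geometry)
        assert abs(img.data.sum() - 5000.0) / 5000.0 < 0.02

    def test_zero_foci_zero_background(self, nucleus_image_geometry):
        img, _ = th.render_nucleus_image(th.FociSpec([], background=0.0), noise=False,
                                         **nucleus_image_geometry)
        assert not img.data.any()

    def test_deterministic_given_seed(self, nucleus_image_geometry):
        spec = th.FociSpec([th.GaussianFocus((1.4, 1.5, 1.6), 3000.0)], seed=11)
        a, _ = th.render_nucleus_image(spec, **nucleus_image_geometry)
        b, _ = th.render_nucleus_image(spec, **nucleus_image_geometry)
        assert np.array_equal(a.data, b.data)

    def test_focus_outside_nucleus_rejected(self, nucleus_image_geometry):
        spec = th.FociSpec([th.GaussianFocus((0.1, 0.1, 0.1), 1000.0)])
        with pytest.raises(ValueError, match="outside"):
            th.render_nucleus_image(spec, **nucleus_image_geometry)

    def test_undersampled_focus_warns(self, nucleus_image_geometry):
        spec = th.FociSpec([th.GaussianFocus((1.4, 1.5, 1.6), 1000.0, sigma_xy=0.01)])
        with pytest.warns(UserWarning, match="undersampled"):
            th.render_nucleus_image(spec, noise=False, **nucleus_image_geometry)

    def test_tiff_roundtrip(self, tmp_path, nucleus_image_geometry):
        from telohic.foci import read_tiff, write_tiff

        spec = th.FociSpec([th.GaussianFocus((1.4, 1.5, 1.6), 3000.0)], seed=2)
        img, _ = th.render_nucleus_image(spec, **nucleus_image_geometry)
        p = tmp_path / "img.tif"
        write_tiff(img, p)
        back = read_tiff(p, img.voxel_size, img.nucleus_center, img.nucleus_radius)
        np.testing.assert_allclose(back.data, img.data.astype(np.float32))
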