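import numpy as np
import pytest

import telohic as th


@pytest.fixture(scope="session")
def genome16():
    """Default 16-chromosome toy karyotype (32 telomeres, rDNA on chrXII)."""
    return th.build_toy_genome()


@pytest.fixture(scope="session")
def genome2():
    return th.build_toy_genome(2, [(100_000, 200_000), (150_000, 120_000)])


@pytest.fixture(scope="session")
def bead_bins16(genome16):
    """One 20-kb bin per bead for the 16-chromosome genome."""
    fm = th.uniform_fragment_map(genome16, 20_000)
    return fm, th.bin_fragments(fm, 1)


@pytest.fixture(scope="session")
def matched_runs(genome16, bead_bins16):
    """Matched-seed G0 vs G1 end-to-end runs (structure -> sampled map ->
    SCN-normalized matrix -> reconstruction), shared across analysis tests."""
    fm, bins = bead_bins16
    out = {}
    for mode in ("G0_hypercluster", "G1_rabl"):
        cfg = th.NucleusConfig(mode=mode, seed=21)
        s = th.simulate_structure(genome16, cfg)
        M = th.structure_to_contact_map(s, bins, n_contacts=300_000, seed=21)
        Mn = th.scn_normalize(th.filter_bins(M))
        out[mode] = {"structure": s, "normalized": Mn}
    return out


@pytest.fixture(scope="session")
def nucleus_image_geometry():
    return dict(
        shape=(16, 48, 48),
        voxel_size=(0.2, 0.065, 0.065),
        nucleus_center=(1.56, 1.56, 1.6),
        nucleus_radius=1.2,
    )


def well_separated_centers():
    """Three focus positions > 4 PSF sigma apart inside the test nucleus."""
    return [(1.0, 1.0, 1.2), (2.1, 1.2, 2.0), (1.4, 2.3, 1.4)]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
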