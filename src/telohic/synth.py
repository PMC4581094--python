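"""Ground-truthed synthetic inputs for every pipeline stage.

Four generators:

* bead-chain chromosome configurations inside a spherical nucleus, in a
  G1 Rabl-like mode (centromeres clustered at a spindle-pole-body point
  near the periphery, telomeres tethered to the nuclear envelope), a G0
  mode (all 32 chromosome ends gathered in a single interior hypercluster)
  or an unconstrained uniform mode;
* raw contact maps sampled from a structure with contact probability
  inversely proportional to 3D bead distance (``c0 / d**exponent``);
* mapped read-pair tables sampled from a contact-probability matrix, with
  planted PCR duplicates and low-mapping-quality mates;
* 3D nucleus images with diffraction-limited Gaussian foci, Poisson shot
  noise and Gaussian read noise.

Every generator takes an explicit seed and is deterministic given it.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import BinTable, GenomeModel, RestrictionFragmentMap
from .hic import PAIR_COLUMNS, ContactMatrix

__all__ = [
    "NucleusConfig",
    "Structure3D",
    "GaussianFocus",
    "FociSpec",
    "Image3D",
    "simulate_structure",
    "expected_contact_map",
    "structure_to_contact_map",
    "simulate_read_pairs",
    "render_nucleus_image",
    "focus_intensity_for_snr",
]

BEAD_SIZE = 20_000  # bp per bead
BOND_LENGTH = 0.15  # um between consecutive 20-kb beads


@dataclass(frozen=True)
class NucleusConfig:
    """Nuclear geometry and organization mode for structure simulation.

    ``radius`` in um. ``mode``: ``G1_rabl`` (Rabl: centromeres within
    ``tether_tolerance`` of a point near the periphery on the SPB side,
    chromosome ends on the envelope), ``G0_hypercluster`` (all chromosome
    ends within ``cluster_radius`` of one interior point closer than
    radius/3 to the center) or ``uniform``. The rDNA is confined to a
    peripheral sector opposite the SPB in both organized modes.
    """

    radius: float = 1.0
    mode: str = "G1_rabl"
    spb_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    cluster_radius: float = 0.1
    tether_tolerance: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.mode not in ("G1_rabl", "G0_hypercluster", "uniform"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0 < self.cluster_radius < self.radius:
            raise ValueError("cluster_radius must lie in (0, radius)")
        if not 0 < self.tether_tolerance < self.radius:
            raise ValueError("tether_tolerance must lie in (0, radius)")


@dataclass
class Structure3D:
    """Bead-chain coordinates with per-bead role labels.

    ``chrom``/``bead`` identify each bead (bead index is per chromosome,
    one bead per 20 kb), ``coords`` is (n, 3) in ``units`` (um for
    simulated structures, dimensionless for reconstructions until
    rescaling, then units of 10 nm).
    """

    chrom: np.ndarray
    bead: np.ndarray
    coords: np.ndarray
    labels: np.ndarray
    units: str = "um"

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.bead = np.asarray(self.bead, dtype=np.int64)
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.labels = np.asarray(self.labels, dtype=object)

    @property
    def n_beads(self) -> int:
        return len(self.coords)

    def chrom_order(self) -> list[str]:
        order, seen = [], set()
        for c in self.chrom:
            if c not in seen:
                seen.add(c)
                order.append(c)
        return order

    def beads_of(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.chrom == chrom)

    def terminal_indices(self) -> dict[str, tuple[int, int]]:
        """First and last bead (row index) of each chromosome present."""
        out = {}
        for c in self.chrom_order():
            idx = self.beads_of(c)
            out[c] = (int(idx[np.argmin(self.bead[idx])]), int(idx[np.argmax(self.bead[idx])]))
        return out

    def pairwise_distances(self) -> np.ndarray:
        d = self.coords[:, None, :] - self.coords[None, :, :]
        return np.sqrt((d ** 2).sum(-1))

    def write_tsv(self, path) -> None:
        df = pd.DataFrame(
            {
                "chrom": self.chrom,
                "bead": self.bead,
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "z": self.coords[:, 2],
                "label": self.labels,
            }
        )
        with open(path, "w") as fh:
            fh.write(f"#units={self.units}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "Structure3D":
        units = "um"
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#units="):
                units = first.strip().split("=", 1)[1]
                df = pd.read_csv(fh, sep="\t")
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t")
        return cls(
            df["chrom"].to_numpy(),
            df["bead"].to_numpy(),
            df[["x", "y", "z"]].to_numpy(float),
            df["label"].to_numpy(),
            units=units,
        )


# --- bead-chain structure generation -----------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector")
    return v / n


def _sample_in_ball(rng, center, r, R_max, tries=200):
    """Uniform point in ball(center, r) intersected with the nucleus ball(0, R_max)."""
    for _ in range(tries):
        p = center + r * _rand_ball(rng)
        if np.linalg.norm(p) <= R_max:
            return p
    raise RuntimeError("could not place point inside nucleus")


def _rand_ball(rng) -> np.ndarray:
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    return v * rng.uniform() ** (1 / 3)


def _rand_dir(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _bridge(rng, p0, p1, n_steps, bond, radius):
    """Fixed-step biased walk from p0 reaching p1 in exactly n_steps steps.

    Intermediate beads stay inside the nucleus; requires
    |p1 - p0| <= 0.95 * n_steps * bond.
    """
    path = [np.asarray(p0, float)]
    cur = path[0]
    for j in range(1, n_steps):
        remaining = n_steps - j  # steps left after this one lands
        to_target = p1 - cur
        d = np.linalg.norm(to_target)
        u_t = to_target / d if d > 1e-12 else _rand_dir(rng)
        alpha = min(1.0, max(0.05, (d / max((remaining + 1) * bond, 1e-12)) ** 2))
        placed = None
        for _ in range(30):
            step = _unit(alpha * u_t + (1 - alpha) * _rand_dir(rng))
            cand = cur + bond * step
            if np.linalg.norm(cand) <= radius and np.linalg.norm(p1 - cand) <= 0.95 * remaining * bond:
                placed = cand
                break
        if placed is None:
            # straight toward the target: always feasible inside a convex nucleus
            # half-bond standoff avoids coincident beads when already close
            placed = cur + bond * u_t if d > bond else p1 - 0.5 * bond * u_t
            r = np.linalg.norm(placed)
            if r > radius:
                placed = placed * (radius / r)
        cur = placed
        path.append(cur)
    path.append(np.asarray(p1, float))
    return path[1:]  # beads after p0


def _free_walk(rng, p0, n_steps, bond, radius):
    path = []
    cur = np.asarray(p0, float)
    for _ in range(n_steps):
        for _ in range(50):
            cand = cur + bond * _rand_dir(rng)
            if np.linalg.norm(cand) <= radius:
                break
        else:
            cand = cur + bond * _unit(-cur)
        cur = cand
        path.append(cur)
    return path


def _rdna_sector_point(rng, direction, radius, near=None, reach=None, tries=400):
    """Point in the peripheral sector (cone half-angle 45 deg around
    ``direction``, radial range 0.55-0.9 R), optionally within ``reach`` of
    ``near``."""
    for _ in range(tries):
        d = _rand_dir(rng)
        if np.dot(d, direction) < np.cos(np.deg2rad(45)):
            continue
        p = d * rng.uniform(0.55, 0.90) * radius
        if near is not None and np.linalg.norm(p - near) > reach:
            continue
        return p
    raise RuntimeError("could not sample rDNA sector point")


def simulate_structure(
    genome: GenomeModel,
    config: NucleusConfig,
    bead_size: int = BEAD_SIZE,
    bond_length: float = BOND_LENGTH,
    max_tries: int = 500,
) -> Structure3D:
    """Generate a bead-chain nuclear structure (one bead per 20 kb).

    Chains are constrained random walks with fixed bond length: anchor
    beads (chromosome ends, centromeres, rDNA beads) are placed to satisfy
    the mode's constraints, then the intervening beads are filled in with
    biased fixed-step bridges that stay inside the nucleus. Deterministic
    given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    R = config.radius
    spb = _unit(np.asarray(config.spb_direction, float))
    rdna_dir = -spb

    if config.mode == "G0_hypercluster":
        hub = _rand_ball(rng) * (R / 3.0) * 0.99
    spb_point = spb * (R - 2 * config.tether_tolerance)

    chroms_out, beads_out, coords_out, labels_out = [], [], [], []

    for c in genome.chromosomes:
        n_k = int(np.ceil(c.length / bead_size))
        if n_k < 2:
            raise ValueError(f"{c.name}: chromosome shorter than two beads")
        cen_bead = min(int(c.centromere_pos // bead_size), n_k - 1)
        labels = np.array(["body"] * n_k, dtype=object)
        labels[0] = labels[-1] = "subtelomere"
        labels[cen_bead] = "centromere"
        rdna_beads: list[int] = []
        if c.rdna_interval is not None:
            s, e = c.rdna_interval
            rdna_beads = sorted(
                set(range(int(s // bead_size), min(int((e - 1) // bead_size) + 1, n_k)))
            )
            for b in rdna_beads:
                labels[b] = "rdna"

        # anchor beads along the chain, in order
        anchor_beads = sorted({0, cen_bead, n_k - 1} | set(rdna_beads))

        placed = None
        for attempt in range(max_tries):
            anchors: dict[int, np.ndarray] = {}
            try:
                if config.mode == "uniform":
                    break  # no anchors
                # centromere first, then chromosome ends within reach, then rDNA
                reach_l = 0.90 * max(cen_bead, 1) * bond_length
                reach_r = 0.90 * max(n_k - 1 - cen_bead, 1) * bond_length
                if config.mode == "G1_rabl":
                    cen = _sample_in_ball(rng, spb_point, config.tether_tolerance, R)
                    anchors[cen_bead] = cen
                    for bead, reach in ((0, reach_l), (n_k - 1, reach_r)):
                        for _ in range(400):
                            p = _rand_dir(rng) * rng.uniform(R - config.tether_tolerance, R)
                            if np.linalg.norm(p - cen) <= reach:
                                anchors[bead] = p
                                break
                        else:
                            raise RuntimeError(
                                f"{c.name}: no envelope point within reach {reach:.2f} um "
                                f"of the centromere anchor"
                            )
                else:  # G0_hypercluster
                    cen = _sample_in_ball(
                        rng, hub, 0.80 * min(reach_l, reach_r), R
                    )
                    anchors[cen_bead] = cen
                    anchors[0] = _sample_in_ball(rng, hub, config.cluster_radius, R)
                    anchors[n_k - 1] = _sample_in_ball(rng, hub, config.cluster_radius, R)
                prev = None
                for b in rdna_beads:
                    near, reach = None, None
                    if prev is not None:
                        near, reach = anchors[prev], 0.90 * (b - prev) * bond_length
                    else:
                        near, reach = anchors[cen_bead], 0.90 * abs(b - cen_bead) * bond_length
                    anchors[b] = _rdna_sector_point(rng, rdna_dir, R, near, reach)
                    prev = b
                # feasibility: consecutive anchors reachable
                ok = True
                for a, b in zip(anchor_beads[:-1], anchor_beads[1:]):
                    if np.linalg.norm(anchors[b] - anchors[a]) > 0.95 * (b - a) * bond_length:
                        ok = False
                        break
                if ok:
                    placed = anchors
                    break
            except RuntimeError:
                continue
        else:
            raise RuntimeError(
                f"{c.name}: could not satisfy {config.mode} constraints after {max_tries} "
                f"attempts (cluster_radius={config.cluster_radius}, "
                f"tether_tolerance={config.tether_tolerance}, bond={bond_length} um); "
                f"constraints are infeasible for this geometry"
            )

        coords = np.zeros((n_k, 3))
        if config.mode == "uniform":
            start = _rand_ball(rng) * 0.8 * R
            coords[0] = start
            walk = _free_walk(rng, start, n_k - 1, bond_length, R)
            coords[1:] = np.asarray(walk)
        else:
            assert placed is not None
            coords[0] = placed[0]
            for a, b in zip(anchor_beads[:-1], anchor_beads[1:]):
                seg = _bridge(rng, placed[a], placed[b], b - a, bond_length, R)
                coords[a + 1 : b + 1] = np.asarray(seg)

        chroms_out.extend([c.name] * n_k)
        beads_out.extend(range(n_k))
        coords_out.append(coords)
        labels_out.extend(labels)

    return Structure3D(
        np.asarray(chroms_out, dtype=object),
        np.asarray(beads_out),
        np.vstack(coords_out),
        np.asarray(labels_out, dtype=object),
        units="um",
    )


# --- contact-map sampling ----------------------------------------------

def expected_contact_map(
    structure: Structure3D, c0: float = 1.0, exponent: float = 1.0
) -> np.ndarray:
    """Dense expected contact frequencies ``c0 / d**exponent`` (zero diagonal)."""
    D = structure.pairwise_distances()
    off = ~np.eye(len(D), dtype=bool)
    if np.any(D[off] == 0):
        raise ValueError("degenerate structure: coincident beads")
    F = np.zeros_like(D)
    F[off] = c0 / D[off] ** exponent
    return F


def structure_to_contact_map(
    structure: Structure3D,
    bins: BinTable,
    c0: float = 1.0,
    n_contacts: int = 1_000_000,
    seed: int = 0,
    exponent: float = 1.0,
) -> ContactMatrix:
    """Sample a raw contact-count matrix from a bead structure.

    Unordered bead pairs are drawn with probability proportional to
    ``c0 / d(i, j)**exponent`` (self-pairs excluded); requires one bead per
    bin. The returned matrix is symmetric with the full pair count on each
    off-diagonal cell pair.
    """
    n = structure.n_beads
    if len(bins) != n:
        raise ValueError(f"bead/bin mismatch: {n} beads vs {len(bins)} bins")
    W = expected_contact_map(structure, c0=c0, exponent=exponent)
    iu = np.triu_indices(n, k=1)
    w = W[iu]
    p = w / w.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_contacts, p)
    M = np.zeros((n, n))
    M[iu] = counts
    M = M + M.T
    return ContactMatrix(M, bins, stage="raw")


# --- read-pair simulation ----------------------------------------------

_BASES = np.array(list("ACGT"))


def simulate_read_pairs(
    contact_probs: ContactMatrix,
    frag_map: RestrictionFragmentMap,
    n_pairs: int = 10_000,
    dup_fraction: float = 0.0,
    lowq_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Sample mapped read pairs from a bin-pair probability matrix.

    Bin pairs are drawn from ``contact_probs`` (normalized internally over
    unordered pairs including the diagonal); each mate lands at a uniform
    position inside a uniformly chosen fragment of its bin. A
    ``dup_fraction`` of pairs gets one exact PCR duplicate appended (same
    coordinates, strands and 6-nt tag); each mate independently receives a
    mapping quality <= 40 with probability ``lowq_fraction``, > 40
    otherwise. Returns the shuffled pair table and a planted-truth dict
    with per-bin-pair counts (``pair_counts`` for all sampled pairs,
    ``clean_pair_counts`` for pairs with both mates unambiguous).
    """
    if not 0 <= dup_fraction <= 1 or not 0 <= lowq_fraction <= 1:
        raise ValueError("dup_fraction and lowq_fraction must be in [0, 1]")
    bins = contact_probs.bins
    n = contact_probs.n
    rng = np.random.default_rng(seed)

    iu = np.triu_indices(n, k=0)
    w = contact_probs.matrix[iu].astype(float)
    if w.sum() <= 0:
        raise ValueError("contact_probs has no mass")
    p = w / w.sum()
    counts = rng.multinomial(n_pairs, p)
    pair_idx = np.repeat(np.arange(len(p)), counts)
    b1 = contact_probs.retained[iu[0][pair_idx]]
    b2 = contact_probs.retained[iu[1][pair_idx]]

    def sample_positions(bin_ids):
        chroms = bins.chrom[bin_ids]
        pos = np.empty(len(bin_ids), dtype=np.int64)
        for c in np.unique(chroms.astype(str)):
            sel = np.flatnonzero(chroms == c)
            frags = frag_map.fragments[c]
            lo = bins.frag_lo[bin_ids[sel]]
            hi = bins.frag_hi[bin_ids[sel]]
            fi = lo + (rng.random(len(sel)) * (hi - lo)).astype(np.int64)
            s, e = frags[fi, 0], frags[fi, 1]
            pos[sel] = s + (rng.random(len(sel)) * (e - s)).astype(np.int64)
        return chroms, pos

    c1, p1 = sample_positions(b1)
    c2, p2 = sample_positions(b2)
    strands = np.array(["+", "-"])
    s1 = strands[rng.integers(0, 2, n_pairs)]
    s2 = strands[rng.integers(0, 2, n_pairs)]
    lowq1 = rng.random(n_pairs) < lowq_fraction
    lowq2 = rng.random(n_pairs) < lowq_fraction
    q1 = np.where(lowq1, rng.integers(0, 41, n_pairs), rng.integers(41, 61, n_pairs))
    q2 = np.where(lowq2, rng.integers(0, 41, n_pairs), rng.integers(41, 61, n_pairs))
    umis = np.array(["".join(row) for row in _BASES[rng.integers(0, 4, (n_pairs, 6))]])

    df = pd.DataFrame(
        {
            "chrom1": c1, "pos1": p1, "strand1": s1, "mapq1": q1,
            "chrom2": c2, "pos2": p2, "strand2": s2, "mapq2": q2,
            "umi": umis,
        }
    )

    truth_counts = np.zeros((len(bins), len(bins)))
    np.add.at(truth_counts, (b1, b2), 1.0)
    off = b1 != b2
    np.add.at(truth_counts, (b2[off], b1[off]), 1.0)
    clean = ~(lowq1 | lowq2)
    clean_counts = np.zeros_like(truth_counts)
    np.add.at(clean_counts, (b1[clean], b2[clean]), 1.0)
    offc = clean & off
    np.add.at(clean_counts, (b2[offc], b1[offc]), 1.0)

    dup_mask = rng.random(n_pairs) < dup_fraction
    dups = df.loc[dup_mask]
    out = pd.concat([df, dups], ignore_index=True)
    out = out.sample(frac=1.0, random_state=int(rng.integers(0, 2**31 - 1))).reset_index(drop=True)

    truth = {
        "pair_counts": truth_counts,
        "clean_pair_counts": clean_counts,
        "n_sampled": int(n_pairs),
        "n_duplicates": int(dup_mask.sum()),
        "n_lowq_pairs": int((~clean).sum()),
    }
    return out, truth


# --- nucleus image rendering -------------------------------------------

@dataclass(frozen=True)
class GaussianFocus:
    """A planted diffraction-limited focus: center (x, y, z) in um,
    integrated intensity in photons, lateral and axial Gaussian widths."""

    center: tuple[float, float, float]
    intensity: float
    sigma_xy: float = 0.13
    sigma_z: float = 0.30


@dataclass
class FociSpec:
    foci: list[GaussianFocus] = field(default_factory=list)
    background: float = 100.0
    read_noise_sd: float = 2.0
    seed: int = 0


@dataclass
class Image3D:
    """Voxel stack (z, y, x) with physical voxel sizes and a spherical nucleus."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]  # (dz, dy, dx) um
    nucleus_center: tuple[float, float, float]  # (x, y, z) um
    nucleus_radius: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("image must be 3D (z, y, x)")
        if min(self.voxel_size) <= 0:
            raise ValueError("voxel sizes must be positive")

    def nucleus_mask(self) -> np.ndarray:
        nz, ny, nx = self.data.shape
        dz, dy, dx = self.voxel_size
        cx, cy, cz = self.nucleus_center
        z = (np.arange(nz) + 0.5) * dz
        y = (np.arange(ny) + 0.5) * dy
        x = (np.arange(nx) + 0.5) * dx
        Z, Y, X = np.meshgrid(z, y, x, indexing="ij")
        return (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 <= self.nucleus_radius ** 2


def _axis_mass(centers_edge0, n, d, mu, sigma):
    """Integral of a unit 1D Gaussian over each voxel along one axis."""
    from scipy.special import erf

    edges = centers_edge0 + np.arange(n + 1) * d
    u = (edges - mu) / (np.sqrt(2) * sigma)
    cdf = 0.5 * (1 + erf(u))
    return np.diff(cdf)


def render_nucleus_image(
    spec: FociSpec,
    shape: tuple[int, int, int] = (16, 48, 48),
    voxel_size: tuple[float, float, float] = (0.2, 0.065, 0.065),
    nucleus_center: tuple[float, float, float] | None = None,
    nucleus_radius: float = 0.9,
    noise: bool = True,
) -> tuple[Image3D, dict]:
    """Render planted Gaussian foci plus background into a noisy 3D stack.

    Each focus contributes its integrated intensity split over voxels by
    exact per-axis Gaussian integrals; the background fills the spherical
    nucleus mask. With ``noise=True``, Poisson shot noise is applied and
    Gaussian read noise added. Returns the image and the planted truth.
    """
    nz, ny, nx = shape
    dz, dy, dx = voxel_size
    if nucleus_center is None:
        nucleus_center = (nx * dx / 2, ny * dy / 2, nz * dz / 2)
    img = Image3D(np.zeros(shape), voxel_size, nucleus_center, nucleus_radius)
    mask = img.nucleus_mask()
    if spec.background < 0:
        raise ValueError("background must be nonnegative")

    clean = np.zeros(shape)
    for f in spec.foci:
        fx, fy, fz = f.center
        r = np.linalg.norm(np.asarray(f.center) - np.asarray(nucleus_center))
        if r > nucleus_radius:
            raise ValueError(f"focus at {f.center} outside the nucleus")
        if f.sigma_xy < dx / 2 or f.sigma_z < dz / 2:
            warnings.warn("focus width below half a voxel: undersampled")
        mz = _axis_mass(0.0, nz, dz, fz, f.sigma_z)
        my = _axis_mass(0.0, ny, dy, fy, f.sigma_xy)
        mx = _axis_mass(0.0, nx, dx, fx, f.sigma_xy)
        clean += f.intensity * mz[:, None, None] * my[None, :, None] * mx[None, None, :]
    clean += spec.background * mask

    if noise:
        rng = np.random.default_rng(spec.seed)
        data = rng.poisson(clean).astype(float)
        data += rng.normal(0.0, spec.read_noise_sd, size=shape)
        data = np.clip(data, 0.0, None)
    else:
        data = clean
    img.data = data
    truth = {
        "foci": [
            {
                "center": list(f.center),
                "intensity": float(f.intensity),
                "sigma_xy": float(f.sigma_xy),
                "sigma_z": float(f.sigma_z),
            }
            for f in spec.foci
        ],
        "background": float(spec.background),
        "read_noise_sd": float(spec.read_noise_sd),
        "nucleus_center": list(nucleus_center),
        "nucleus_radius": float(nucleus_radius),
    }
    return img, truth


def focus_intensity_for_snr(
    snr: float,
    background: float = 100.0,
    read_noise_sd: float = 2.0,
    sigma_xy: float = 0.13,
    sigma_z: float = 0.30,
    voxel_size: tuple[float, float, float] = (0.2, 0.065, 0.065),
) -> float:
    """Integrated intensity giving a peak-voxel signal of ``snr`` times the
    background noise sd (shot noise plus read noise, in quadrature)."""
    dz, dy, dx = voxel_size
    from scipy.special import erf

    def central(d, s):
        return float(erf(d / (2 * np.sqrt(2) * s)))

    peak_frac = central(dz, sigma_z) * central(dy, sigma_xy) * central(dx, sigma_xy)
    noise_sd = np.sqrt(background + read_noise_sd ** 2)
    return snr * noise_sd / peak_frac
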