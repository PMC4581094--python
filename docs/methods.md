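# Methods

This note documents the models, parameter choices and numerical decisions
behind `telohic`, and what the synthetic-data validation does and does not
demonstrate about real data.

## Genome model

Coordinates are 0-based, half-open throughout (BED convention). In-silico
digestion cuts at the first base of each recognition-site occurrence
(DpnII cuts 5′ of `GATC`; any fixed offset within the site is equivalent
once fragments are binned). Fragments tile each chromosome exactly;
binning groups `F` consecutive fragments (default 20, with `F = 10` for
finer maps and `F = 1` for fragment-resolution analyses), keeping partial
terminal bins so the bin ↔ fragment correspondence stays lossless. Only
nuclear chromosomes are modeled; the mitochondrial genome is excluded.

The default toy karyotype mirrors the 16 *S. cerevisiae* chromosomes with
arm lengths rounded to the kb (total ≈ 12.07 Mb, 32 telomeres) and an
rDNA interval on the right arm of chromosome XII. It is a geometry
scaffold for simulation, not an annotation resource.

## Bead-chain structure simulation

Each chromosome is a chain of 20-kb beads with fixed bond length
**0.15 μm** inside a spherical nucleus (default radius 1 μm). The bond
length encodes a chromatin compaction of ~7.5 nm/kb — between a naive
30-nm-fiber estimate and highly condensed chromatin — chosen once so that
all tethering constraints below are simultaneously satisfiable for every
chromosome (in particular chromosome XII, whose centromere, rDNA sector
and both telomeres are all constrained). No polymer-physics realism is
claimed; the generator's only job is to plant the qualitative features the
pipeline must recover.

Anchor beads are placed first, then intervening beads are filled in by a
biased fixed-step random bridge that stays inside the nucleus; infeasible
constraint sets fail after a bounded number of retries with a diagnostic.

* **G1 Rabl mode** — centromere beads within `tether_tolerance`
  (default 0.15 μm) of a point near the periphery on the SPB axis;
  terminal beads on the envelope shell (within `tether_tolerance` of the
  surface), subject to chain reach, which naturally polarizes short-arm
  telomeres toward the SPB side.
* **G0 hypercluster mode** — all 32 terminal beads within
  `cluster_radius` of a single interior hub sampled closer than R/3 to
  the center. The physical hypercluster radius is not experimentally
  constrained; the default 0.1 μm is a free parameter.
* **Both modes** — rDNA beads confined to a peripheral sector (cone of
  45° around the anti-SPB axis, radial range 0.55–0.9 R), mimicking the
  nucleolus opposite the spindle pole body.
* **Uniform mode** — unconstrained confined random walk; used as a
  neutral substrate for round-trip tests.

## Contact-map sampling

Expected contact frequency between beads is `c0 / d**α` with **α = 1 by
default**, so that the reconstruction stage's inversion (distance =
1/frequency) is exact in the noiseless limit; other exponents are exposed
as an option. Raw maps draw `n_contacts` unordered bead pairs from a
multinomial over these weights. Read-pair simulation places each mate at a
uniform position within a uniformly chosen fragment of its bin, appends
exact PCR duplicates (same coordinates, strands and 6-nt tag) for a
configurable fraction of pairs, and gives each mate a mapping quality ≤ 40
with a configurable probability. Every generator consumes one explicit
seed stream per operation.

## Hi-C pipeline

Filtering is strict `MAPQ > 40` on both mates; duplicates collapse on
(both coordinates, both strands, tag) — strands are part of the key
because paired-end duplicates share the full orientation. Bin filtering
masks zero-coverage bins and bins below the 0.01 quantile of nonzero
marginals; the quantile is a package choice (the filtering rule used on
the real data is not published) and is exposed as a parameter.

SCN iterates column normalization, row normalization and symmetrization
`(M + Mᵀ)/2` until every marginal is within `tol` (default 1e-6) of 1,
failing loudly after `max_iter` (default 200) rounds. The per-round
symmetrization makes the output exactly symmetric at every iterate; its
fixed point differs from the pure diagonal-scaling (Sinkhorn `D A D`)
solution by O(1e-3) on small matrices — both are doubly stochastic, and
the tests pin the behavior of this variant.

## Reconstruction

Shortest paths are computed with Dijkstra from every node on the graph
with edge weights 1/frequency (intra-bin diagonal entries are excluded
from graph construction); a disconnected graph is an error that reports
the components. Classical MDS double-centers −½D², eigendecomposes, and
uses the top three nonnegative eigenvalues; negative eigenvalues of
non-Euclidean inputs are clipped to zero (standard Torgerson treatment),
and eigenvalues below 1e-10 of the spectral scale are zeroed exactly so
degenerate directions give exactly-zero coordinates.

Rescaling first equalizes convex-hull volumes between the two structures,
then matches each hull volume to the sphere of its stated nuclear
diameter (defaults 1.5 μm for G0, 1.7 μm for G1), emitting coordinates in
units of 10 nm. A variant (`method="diameter"`) applies a linear diameter
ratio instead of per-structure sphere matching; volume matching is the
default because it interprets "account for nuclear size" volumetrically.
The telomere bead of an arm is the first/last *retained* bead of its
chromosome — the subtelomeric extent in beads is not otherwise defined at
20-kb resolution.

## Contact statistics

Subtelomere profiles require the matrix resolution to be at least as fine
as the window (3-kb windows are meant for fragment-level or ≤ 3-kb maps;
the bead-resolution demonstrations use 20-kb windows). "Other
subtelomeres" means the offset-0 windows of all arms of *other*
chromosomes; both arms of the focal chromosome are excluded to avoid
trivially high cis contacts (a flag restores same-chromosome arms).
Random-segment controls sample 35-kb segments excluding the terminal
30 kb of each arm so they cannot overlap subtelomeres, and report a
delete-one-segment jackknife standard error: segment pairs share
segments, so a naive sd/√(n_pairs) would understate the sampling
variance. The centromere score is the mean normalized contact between
inter-chromosomal pairs of centromere-window bins.

## Focus quantification

The detection procedure is this package's operational definition (the
original in-house tool is not published): Gaussian smoothing at physical
width `sigma` (default 0.08 μm), background = median of the smoothed
stack inside the nucleus, noise scale = 1.4826 × MAD, candidates above
background + `k`·sd (default k = 5), 26-connected components with at
least `min_voxels` (default 4) voxels. Focus intensity is
background-subtracted **aperture photometry**: the sum of (raw −
background) over an ellipsoid of 3.5 PSF widths (defaults σ_xy = 0.13 μm,
σ_z = 0.30 μm) around the intensity-weighted centroid, with contested
voxels assigned to the nearest centroid in PSF-scaled distance.
Integrating only the thresholded component would truncate ~20 % of a 3D
Gaussian's mass near the detection limit; the 3.5σ aperture captures
~99 % of it. Two background subtleties matter in small nuclei: background
is subtracted only inside the nucleus mask (apertures may legitimately
cross the envelope, where there is no background), and it is re-estimated
from focus-free voxels once apertures are known, because foci can occupy
enough of a yeast nucleus to bias the whole-nucleus median.

The hypercluster call is strict: 1 or 2 foci and the brightest focus
strictly above the 95th percentile of the pooled reference focus
intensities (computed over all reference foci, not per-cell maxima; a
parameter could switch this). Nuclear zoning uses three *equal-area*
concentric zones in the focal plane (boundaries at R·√⅓ and R·√⅔, zone 3
innermost), the standard yeast zoning convention; an equal-radial-thirds
variant is available.

Mann–Whitney U is computed from midrank sums; p-values are exact by
enumeration for combined samples of at most 12 without ties (delegated to
scipy's exact method, which enumerates the same null) and otherwise use
the normal approximation with tie correction. The two-proportion z test
is the pooled closed form.

## What the synthetic validation shows — and what it does not

The simulations validate *recovery*: SCN balances to 1e-6; the noiseless
contact→distance→embedding round trip reproduces planted distances to
float precision (direct edges dominate because Euclidean distances obey
the triangle inequality); matched-seed G0/G1 runs at 10⁶ contacts
reproduce the expected contrasts (closer telomeres and stronger terminal
contacts in G0, stronger centromere clustering in G1, bias-free random
controls); planted foci are counted and integrated correctly at SNR ≥ 10
and separations ≥ 4σ.

They do not emulate: distance-dependent polymer contact statistics beyond
1/d, restriction-site density biases, ligation artifacts (self-circles,
religations), chromatin heterogeneity, optical aberrations or
camera-specific noise, or nucleus segmentation (the nucleus sphere/mask is
an input). Quantities tied to real biology — absolute focus-count
distributions, the fivefold intensity increase, zone-3 percentages of
real hyperclusters — depend on the real data and are outside what these
tests can establish.

## Problem sizes

Defaults used by the test suite and acceptance script: 16-chromosome
~12-Mb genome (≈ 604 retained 20-kb bins), 10⁶ sampled contacts per
condition, 200 rendered images for count-recovery rates, 1000 cells for
hypercluster-fraction recovery, 10⁵ points for the zoning null; these
sizes give tight Monte-Carlo intervals while keeping a full run in tens
of seconds.
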