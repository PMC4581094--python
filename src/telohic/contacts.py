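"""Contact-map statistics: subtelomere contact profiles with distance from
the telomere, random-segment coverage controls, centromere contact scores,
and inter-chromosome submatrix views.

A profile answers: how strongly does chromatin at a given distance from a
telomere contact the terminal windows of the *other* chromosomes? In a
telomere-hypercluster nucleus the profile peaks sharply at offset 0; a
35-kb random-segment control checks that this is not a coverage artifact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeModel
from .hic import ContactMatrix

__all__ = [
    "ContactProfile",
    "RandomSegmentControl",
    "subtelomere_contact_profile",
    "random_segment_control",
    "centromere_contact_score",
    "interchromosomal_submatrix",
]


@dataclass
class ContactProfile:
    """Mean contact of each distance-from-telomere window with the terminal
    windows of other chromosomes. ``table`` columns: offset_start,
    offset_end, mean_contact, n_pairs."""

    table: pd.DataFrame
    window: int
    condition: str = ""

    @property
    def values(self) -> np.ndarray:
        return self.table["mean_contact"].to_numpy()

    @property
    def offsets(self) -> np.ndarray:
        return self.table["offset_start"].to_numpy()

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _arm_offsets(M: ContactMatrix, genome: GenomeModel):
    """Per retained bin: (arm key, distance of bin midpoint from its telomere)."""
    chroms = M.bins.chrom[M.retained]
    mids = M.bins.midpoints[M.retained]
    arm_keys = np.empty(len(chroms), dtype=object)
    offsets = np.zeros(len(chroms), dtype=np.int64)
    for c in genome.chromosomes:
        sel = np.flatnonzero(chroms == c.name)
        if not sel.size:
            continue
        left = mids[sel] < c.centromere_pos
        for i, is_left in zip(sel, left):
            if is_left:
                arm_keys[i] = f"{c.name}:L"
                offsets[i] = mids[i]
            else:
                arm_keys[i] = f"{c.name}:R"
                offsets[i] = c.length - mids[i]
    return arm_keys, offsets


def subtelomere_contact_profile(
    M: ContactMatrix,
    genome: GenomeModel,
    window: int = 3000,
    extent: int = 30000,
    include_same_chromosome: bool = False,
    condition: str = "",
) -> ContactProfile:
    """Mean contact between windows at offset k from each telomere and the
    offset-0 windows of the other chromosomes' arms.

    Bins are assigned to ``window``-bp windows by the distance of their
    midpoint from the arm's telomere; the profile value at offset k is the
    unweighted mean over arms of the mean contact between that arm's
    offset-k bins and the terminal (offset-0) bins of all arms of other
    chromosomes (same-chromosome arms excluded unless
    ``include_same_chromosome``). Arms shorter than ``extent`` contribute
    only their available windows.
    """
    bin_res = int(np.max(M.bins.end[M.retained] - M.bins.start[M.retained]))
    if bin_res > window:
        raise ValueError(
            f"matrix resolution ({bin_res} bp bins) is coarser than the {window}-bp window"
        )
    n_windows = extent // window
    arm_keys, offsets = _arm_offsets(M, genome)
    win_idx = offsets // window

    arms = sorted({k for k in arm_keys if k is not None})
    zero_bins = {a: np.flatnonzero((arm_keys == a) & (win_idx == 0)) for a in arms}
    short_arms = [a for a in arms if (offsets[arm_keys == a].max(initial=0) // window) + 1 < n_windows]
    if short_arms:
        warnings.warn(f"{len(short_arms)} arms shorter than extent: partial profiles")

    rows = []
    for k in range(n_windows):
        vals, n_pairs = [], 0
        for a in arms:
            rows_k = np.flatnonzero((arm_keys == a) & (win_idx == k))
            if not rows_k.size:
                continue
            a_chrom = a.rsplit(":", 1)[0]
            donors = [
                b
                for b in arms
                if b != a
                and (include_same_chromosome or b.rsplit(":", 1)[0] != a_chrom)
            ]
            cols = (
                np.concatenate([zero_bins[b] for b in donors])
                if donors
                else np.array([], dtype=int)
            )
            if not cols.size:
                continue
            block = M.matrix[np.ix_(rows_k, cols)]
            vals.append(block.mean())
            n_pairs += block.size
        rows.append(
            {
                "offset_start": k * window,
                "offset_end": (k + 1) * window,
                "mean_contact": float(np.mean(vals)) if vals else np.nan,
                "n_pairs": n_pairs,
            }
        )
    return ContactProfile(pd.DataFrame(rows), window, condition)


@dataclass
class RandomSegmentControl:
    """Mean pairwise inter-segment contact for random non-telomeric segments.

    ``sem`` is a delete-one-segment jackknife standard error of the mean —
    segment pairs share segments, so naive sd/sqrt(n_pairs) would be
    anti-conservative.
    """

    mean: float
    sd: float
    sem: float
    n_segments: int
    segments: list[tuple[str, int, int]]
    pair_values: np.ndarray


def random_segment_control(
    M: ContactMatrix,
    genome: GenomeModel,
    seg_length: int = 35000,
    n_segments: int = 100,
    seed: int = 0,
    exclude_terminal: int = 30000,
) -> RandomSegmentControl:
    """Coverage-bias control: mean contact between random 35-kb segments.

    Segments are sampled uniformly from the genome, excluding the terminal
    ``exclude_terminal`` bp of each arm so the control cannot overlap
    subtelomeres; the statistic is the mean contact over all unordered
    inter-chromosomal segment pairs. Deterministic given ``seed``.
    """
    if n_segments < 2:
        raise ValueError("need at least 2 segments")
    rng = np.random.default_rng(seed)
    eligible = []
    for c in genome.chromosomes:
        lo = exclude_terminal
        hi = c.length - exclude_terminal - seg_length
        if hi > lo:
            eligible.append((c.name, lo, hi))
    if not eligible:
        raise ValueError("no chromosome can host a control segment")
    weights = np.array([hi - lo for _, lo, hi in eligible], dtype=float)
    weights /= weights.sum()

    chroms = M.bins.chrom[M.retained]
    mids = M.bins.midpoints[M.retained]
    segments, seg_bins = [], []
    guard = 0
    while len(segments) < n_segments:
        guard += 1
        if guard > 100 * n_segments:
            raise RuntimeError("could not place control segments on retained bins")
        name, lo, hi = eligible[rng.choice(len(eligible), p=weights)]
        start = int(rng.integers(lo, hi))
        sel = np.flatnonzero((chroms == name) & (mids >= start) & (mids < start + seg_length))
        if not sel.size:
            continue
        segments.append((name, start, start + seg_length))
        seg_bins.append(sel)

    pair_vals = []
    pair_segs = []
    for i in range(n_segments):
        for j in range(i + 1, n_segments):
            if segments[i][0] == segments[j][0]:
                continue
            pair_vals.append(M.matrix[np.ix_(seg_bins[i], seg_bins[j])].mean())
            pair_segs.append((i, j))
    if not pair_vals:
        raise ValueError("no inter-chromosomal segment pairs (single-chromosome genome?)")
    pair_vals = np.asarray(pair_vals)
    mean = float(pair_vals.mean())

    # jackknife over segments
    thetas = []
    for i in range(n_segments):
        keep = [v for v, (a, b) in zip(pair_vals, pair_segs) if a != i and b != i]
        if keep:
            thetas.append(np.mean(keep))
    thetas = np.asarray(thetas)
    m = len(thetas)
    sem = float(np.sqrt((m - 1) / m * np.sum((thetas - thetas.mean()) ** 2)))
    return RandomSegmentControl(
        mean, float(pair_vals.std(ddof=1)), sem, n_segments, segments, pair_vals
    )


def centromere_contact_score(M: ContactMatrix, genome: GenomeModel, window: int = 20000) -> float:
    """Mean contact between inter-chromosomal pairs of centromere windows.

    The window of each chromosome is the set of retained bins intersecting
    ``centromere +- window/2``; chromosomes whose centromere bins are all
    masked are excluded with a warning. Requires >= 2 chromosomes.
    """
    chroms = M.bins.chrom[M.retained]
    starts = M.bins.start[M.retained]
    ends = M.bins.end[M.retained]
    cen_bins = {}
    for c in genome.chromosomes:
        lo, hi = c.centromere_pos - window // 2, c.centromere_pos + window // 2
        sel = np.flatnonzero((chroms == c.name) & (starts < hi) & (ends > lo))
        if sel.size:
            cen_bins[c.name] = sel
        else:
            warnings.warn(f"{c.name}: centromere bins masked, chromosome excluded")
    names = list(cen_bins)
    if len(names) < 2:
        raise ValueError("centromere score needs >= 2 chromosomes with retained centromere bins")
    vals = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            vals.append(M.matrix[np.ix_(cen_bins[names[i]], cen_bins[names[j]])].mean())
    return float(np.mean(vals))


def interchromosomal_submatrix(
    M: ContactMatrix, chrom_a: str, chrom_b: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rectangular view of contacts between two chromosomes.

    Returns (submatrix, row bin ids, column bin ids); values are copied
    bit-identically from the parent matrix.
    """
    chroms = M.bins.chrom[M.retained]
    rows = np.flatnonzero(chroms == chrom_a)
    cols = np.flatnonzero(chroms == chrom_b)
    if not rows.size:
        raise KeyError(f"unknown or fully masked chromosome {chrom_a!r}")
    if not cols.size:
        raise KeyError(f"unknown or fully masked chromosome {chrom_b!r}")
    return M.matrix[np.ix_(rows, cols)].copy(), M.retained[rows], M.retained[cols]
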