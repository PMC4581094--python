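"""Genome coordinate system: chromosomes, centromeres, telomeres, rDNA,
in-silico restriction fragments and fragment-group bins.

All coordinates are 0-based, half-open ``[start, end)`` (BED convention).
A restriction fragment map tiles each chromosome without gaps or overlaps;
a bin groups ``F`` consecutive fragments of one chromosome (the last bin of
a chromosome may hold fewer). Bins never span chromosomes and carry a
contiguous genome-wide index starting at 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "ChromosomeSpec",
    "Telomere",
    "GenomeModel",
    "RestrictionFragmentMap",
    "BinTable",
    "build_toy_genome",
    "digest_genome",
    "bin_fragments",
    "uniform_fragment_map",
    "DEFAULT_KARYOTYPE",
]

#: Approximate S. cerevisiae karyotype used by :func:`build_toy_genome`:
#: (name, left arm bp, right arm bp). Arm lengths are rounded to the kb from
#: the reference chromosome lengths and centromere positions; the rDNA
#: repeat array sits on the right arm of chromosome XII.
DEFAULT_KARYOTYPE: list[tuple[str, int, int]] = [
    ("chrI", 151_000, 79_000),
    ("chrII", 238_000, 575_000),
    ("chrIII", 114_000, 203_000),
    ("chrIV", 450_000, 1_082_000),
    ("chrV", 152_000, 425_000),
    ("chrVI", 148_000, 122_000),
    ("chrVII", 497_000, 594_000),
    ("chrVIII", 105_000, 457_000),
    ("chrIX", 355_000, 85_000),
    ("chrX", 436_000, 310_000),
    ("chrXI", 440_000, 227_000),
    ("chrXII", 151_000, 927_000),
    ("chrXIII", 268_000, 656_000),
    ("chrXIV", 629_000, 155_000),
    ("chrXV", 327_000, 764_000),
    ("chrXVI", 556_000, 392_000),
]

DEFAULT_RDNA = ("chrXII", (451_000, 491_000))


@dataclass(frozen=True)
class ChromosomeSpec:
    """One chromosome: total length, centromere position, optional rDNA span."""

    name: str
    length: int
    centromere_pos: int
    rdna_interval: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.name}: length must be positive")
        if not 0 < self.centromere_pos < self.length:
            raise ValueError(
                f"{self.name}: centromere {self.centromere_pos} outside (0, {self.length})"
            )
        if self.rdna_interval is not None:
            s, e = self.rdna_interval
            if not (0 <= s < e <= self.length):
                raise ValueError(f"{self.name}: rDNA interval {self.rdna_interval} invalid")

    @property
    def arm_lengths(self) -> tuple[int, int]:
        """(left, right) arm lengths in bp."""
        return self.centromere_pos, self.length - self.centromere_pos


@dataclass(frozen=True)
class Telomere:
    """A chromosome-arm end locus (coordinate 0 or chromosome length)."""

    chrom: str
    arm: str  # "L" or "R"
    position: int
    arm_length: int


class GenomeModel:
    """Ordered chromosome set with derived telomere list (2 per chromosome)."""

    def __init__(self, chromosomes: Sequence[ChromosomeSpec]):
        if not chromosomes:
            raise ValueError("GenomeModel needs at least one chromosome")
        names = [c.name for c in chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        self.chromosomes: tuple[ChromosomeSpec, ...] = tuple(chromosomes)
        self._by_name = {c.name: c for c in self.chromosomes}

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def chromosome(self, name: str) -> ChromosomeSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    @property
    def telomeres(self) -> list[Telomere]:
        """All 2 × n_chromosomes telomeres, in chromosome order (L then R)."""
        out = []
        for c in self.chromosomes:
            left, right = c.arm_lengths
            out.append(Telomere(c.name, "L", 0, left))
            out.append(Telomere(c.name, "R", c.length, right))
        return out

    def telomeres_by_arm_length(self) -> list[Telomere]:
        """Telomeres sorted by increasing arm length (ties: chromosome name, arm)."""
        return sorted(self.telomeres, key=lambda t: (t.arm_length, t.chrom, t.arm))

    # --- serialization -------------------------------------------------
    def to_yaml(self, path) -> None:
        payload = {
            "chromosomes": [
                {
                    "name": c.name,
                    "length": int(c.length),
                    "centromere_pos": int(c.centromere_pos),
                    "rdna_interval": list(c.rdna_interval) if c.rdna_interval else None,
                }
                for c in self.chromosomes
            ]
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GenomeModel":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        chroms = [
            ChromosomeSpec(
                d["name"],
                int(d["length"]),
                int(d["centromere_pos"]),
                tuple(d["rdna_interval"]) if d.get("rdna_interval") else None,
            )
            for d in payload["chromosomes"]
        ]
        return cls(chroms)

    def __repr__(self) -> str:  # pragma: no cover
        return f"GenomeModel({self.n_chromosomes} chromosomes, {2 * self.n_chromosomes} telomeres)"


def build_toy_genome(
    n_chrom: int = 16,
    arm_lengths: Sequence[tuple[int, int]] | None = None,
    rdna_chrom: str | None = "chrXII",
    rdna_interval: tuple[int, int] | None = None,
) -> GenomeModel:
    """Build a toy genome with ``n_chrom`` chromosomes from arm-length pairs.

    Defaults reproduce a 16-chromosome karyotype mimicking S. cerevisiae
    (so 32 telomeres), with an rDNA interval on chromosome XII. The
    centromere of each chromosome sits at the junction of its two arms.
    """
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if arm_lengths is None:
        if n_chrom > len(DEFAULT_KARYOTYPE):
            raise ValueError("default karyotype provides at most 16 chromosomes")
        entries = DEFAULT_KARYOTYPE[:n_chrom]
        names = [e[0] for e in entries]
        arm_lengths = [(e[1], e[2]) for e in entries]
        if rdna_chrom == "chrXII" and rdna_interval is None and "chrXII" in names:
            rdna_interval = DEFAULT_RDNA[1]
    else:
        if len(arm_lengths) != n_chrom:
            raise ValueError("need one arm-length pair per chromosome")
        names = [f"chr{i + 1}" for i in range(n_chrom)]

    chroms = []
    for name, (left, right) in zip(names, arm_lengths):
        if left <= 0 or right <= 0:
            raise ValueError(f"{name}: arm lengths must be positive, got {(left, right)}")
        rdna = rdna_interval if name == rdna_chrom else None
        chroms.append(ChromosomeSpec(name, left + right, left, rdna))
    return GenomeModel(chroms)


class RestrictionFragmentMap:
    """Per-chromosome ordered half-open fragment intervals tiling each chromosome."""

    def __init__(self, fragments: Mapping[str, np.ndarray], chrom_order: Sequence[str] | None = None):
        self.chrom_order = list(chrom_order) if chrom_order is not None else list(fragments)
        self.fragments: dict[str, np.ndarray] = {}
        for name in self.chrom_order:
            arr = np.asarray(fragments[name], dtype=np.int64).reshape(-1, 2)
            if arr.size:
                if np.any(arr[:, 1] <= arr[:, 0]):
                    raise ValueError(f"{name}: empty or inverted fragment")
                if arr[0, 0] != 0 or np.any(arr[1:, 0] != arr[:-1, 1]):
                    raise ValueError(f"{name}: fragments do not tile the chromosome")
            self.fragments[name] = arr

    def n_fragments(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return len(self.fragments[chrom])
        return sum(len(a) for a in self.fragments.values())

    def chrom_length(self, chrom: str) -> int:
        arr = self.fragments[chrom]
        return int(arr[-1, 1]) if arr.size else 0

    def locate(self, chrom: str, pos: int | np.ndarray) -> np.ndarray:
        """Fragment index (within chromosome) containing each position; -1 if outside."""
        arr = self.fragments[chrom]
        pos = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        if not arr.size:
            return np.full(pos.shape, -1, dtype=np.int64)
        idx = np.searchsorted(arr[:, 0], pos, side="right") - 1
        bad = (pos < 0) | (pos >= arr[-1, 1])
        idx[bad] = -1
        return idx

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#chrom\tstart\tend\tindex\n")
            i = 0
            for name in self.chrom_order:
                for s, e in self.fragments[name]:
                    fh.write(f"{name}\t{s}\t{e}\t{i}\n")
                    i += 1

    @classmethod
    def read_bed(cls, path) -> "RestrictionFragmentMap":
        frags: dict[str, list[tuple[int, int]]] = {}
        order: list[str] = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                chrom, s, e = line.split("\t")[:3]
                if chrom not in frags:
                    frags[chrom] = []
                    order.append(chrom)
                frags[chrom].append((int(s), int(e)))
        return cls({c: np.array(v) for c, v in frags.items()}, order)


def digest_genome(sequences: Iterable, site: str = "GATC") -> RestrictionFragmentMap:
    """In-silico digestion: cut at the first base of each recognition-site
    occurrence (DpnII cuts 5' of GATC; any fixed offset is equivalent for
    binning). Accepts Biopython SeqRecords or ``(name, sequence)`` pairs.
    Zero-length leading fragments are dropped; an empty sequence yields an
    empty fragment list with a warning.
    """
    site = site.upper()
    if not site:
        raise ValueError("recognition site must be nonempty")
    frags: dict[str, np.ndarray] = {}
    order: list[str] = []
    for rec in sequences:
        if hasattr(rec, "seq"):  # Bio.SeqRecord
            name, seq = rec.id, str(rec.seq)
        else:
            name, seq = rec
        seq = seq.upper()
        order.append(name)
        if not seq:
            warnings.warn(f"{name}: empty sequence, no fragments")
            frags[name] = np.empty((0, 2), dtype=np.int64)
            continue
        cuts = [0]
        pos = seq.find(site)
        while pos != -1:
            cuts.append(pos)
            pos = seq.find(site, pos + 1)
        cuts.append(len(seq))
        cuts = sorted(set(cuts))
        arr = np.column_stack([cuts[:-1], cuts[1:]]).astype(np.int64)
        frags[name] = arr[arr[:, 1] > arr[:, 0]]
    return RestrictionFragmentMap(frags, order)


class BinTable:
    """Genome-wide bin index: each bin covers ``F`` consecutive fragments of
    one chromosome (fewer for a chromosome's last bin)."""

    def __init__(
        self,
        chroms: Sequence[str],
        starts: Sequence[int],
        ends: Sequence[int],
        frag_lo: Sequence[int],
        frag_hi: Sequence[int],
        chrom_order: Sequence[str] | None = None,
    ):
        self.chrom = np.asarray(chroms, dtype=object)
        self.start = np.asarray(starts, dtype=np.int64)
        self.end = np.asarray(ends, dtype=np.int64)
        self.frag_lo = np.asarray(frag_lo, dtype=np.int64)  # per-chromosome fragment index
        self.frag_hi = np.asarray(frag_hi, dtype=np.int64)  # half-open
        if chrom_order is None:
            chrom_order, seen = [], set()
            for c in self.chrom:
                if c not in seen:
                    seen.add(c)
                    chrom_order.append(c)
        self.chrom_order = list(chrom_order)
        self._chrom_bins = {c: np.flatnonzero(self.chrom == c) for c in self.chrom_order}

    def __len__(self) -> int:
        return len(self.start)

    @property
    def n_bins(self) -> int:
        return len(self.start)

    def bins_of_chrom(self, chrom: str) -> np.ndarray:
        return self._chrom_bins[chrom]

    @property
    def midpoints(self) -> np.ndarray:
        return (self.start + self.end) // 2

    def locate(self, chrom: str, pos: int | np.ndarray) -> np.ndarray:
        """Genome-wide bin index containing each position; -1 if outside."""
        pos = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        ids = self._chrom_bins.get(chrom)
        if ids is None or not ids.size:
            return np.full(pos.shape, -1, dtype=np.int64)
        starts = self.start[ids]
        k = np.searchsorted(starts, pos, side="right") - 1
        out = np.where((k >= 0) & (pos < self.end[ids[np.clip(k, 0, len(ids) - 1)]]), ids[np.clip(k, 0, len(ids) - 1)], -1)
        out[pos < starts[0]] = -1
        return out

    def bin_of_fragment(self, chrom: str, frag_idx: np.ndarray) -> np.ndarray:
        """Map per-chromosome fragment indices to genome-wide bin ids (-1 outside)."""
        ids = self._chrom_bins[chrom]
        frag_idx = np.atleast_1d(np.asarray(frag_idx, dtype=np.int64))
        lo = self.frag_lo[ids]
        k = np.searchsorted(lo, frag_idx, side="right") - 1
        valid = (frag_idx >= 0) & (k >= 0)
        kk = np.clip(k, 0, len(ids) - 1)
        valid &= frag_idx < self.frag_hi[ids[kk]]
        return np.where(valid, ids[kk], -1)

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#chrom\tstart\tend\tindex\tfrag_lo\tfrag_hi\n")
            for i in range(len(self)):
                fh.write(
                    f"{self.chrom[i]}\t{self.start[i]}\t{self.end[i]}\t{i}\t"
                    f"{self.frag_lo[i]}\t{self.frag_hi[i]}\n"
                )

    @classmethod
    def read_bed(cls, path) -> "BinTable":
        rows = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                rows.append((f[0], int(f[1]), int(f[2]), int(f[4]), int(f[5])))
        return cls(
            [r[0] for r in rows],
            [r[1] for r in rows],
            [r[2] for r in rows],
            [r[3] for r in rows],
            [r[4] for r in rows],
        )


def bin_fragments(frag_map: RestrictionFragmentMap, F: int = 20) -> BinTable:
    """Group every ``F`` consecutive fragments of a chromosome into one bin.

    Yields ``ceil(n_frag / F)`` bins per chromosome; partial terminal bins
    are kept. The default 20 fragments per bin matches genome-wide 3C maps;
    ``F=10`` gives the finer resolution variant and ``F=1`` bins identical
    to fragments.
    """
    if F < 1:
        raise ValueError("F must be >= 1")
    chroms, starts, ends, flo, fhi = [], [], [], [], []
    for name in frag_map.chrom_order:
        arr = frag_map.fragments[name]
        n = len(arr)
        for lo in range(0, n, F):
            hi = min(lo + F, n)
            chroms.append(name)
            starts.append(int(arr[lo, 0]))
            ends.append(int(arr[hi - 1, 1]))
            flo.append(lo)
            fhi.append(hi)
    return BinTable(chroms, starts, ends, flo, fhi, frag_map.chrom_order)


def uniform_fragment_map(genome: GenomeModel, fragment_size: int = 20_000) -> RestrictionFragmentMap:
    """Tile every chromosome with fixed-size fragments (last one partial).

    Convenience for synthetic pipelines where one 20-kb "fragment" per bead
    stands in for a restriction digest at matching resolution.
    """
    if fragment_size < 1:
        raise ValueError("fragment_size must be >= 1")
    frags = {}
    for c in genome.chromosomes:
        edges = np.arange(0, c.length, fragment_size, dtype=np.int64)
        edges = np.append(edges, c.length)
        frags[c.name] = np.column_stack([edges[:-1], edges[1:]])
    return RestrictionFragmentMap(frags, genome.names)
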