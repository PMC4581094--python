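"""From mapped read pairs to filtered, SCN-normalized contact matrices.

The pipeline mirrors a standard 3C/Hi-C workflow: collapse PCR duplicates
(using the 6-nt random adapter tag), drop pairs with an ambiguous mate
(mapping quality <= 40), assign mates to restriction fragments, aggregate
fragments into bins, then filter low-coverage bins and balance the matrix
with sequential component normalization (SCN) so every retained row and
column sums to 1.

Read pairs are handled as a pandas DataFrame with columns
``chrom1 pos1 strand1 mapq1 chrom2 pos2 strand2 mapq2 umi``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .genome import BinTable, RestrictionFragmentMap

__all__ = [
    "PAIR_COLUMNS",
    "ContactMatrix",
    "PreprocessStats",
    "preprocess_pairs",
    "build_contact_matrix",
    "filter_bins",
    "scn_normalize",
    "read_pairs",
    "write_pairs",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_matrix_mtx",
    "write_matrix_mtx",
]

PAIR_COLUMNS = [
    "chrom1", "pos1", "strand1", "mapq1",
    "chrom2", "pos2", "strand2", "mapq2",
    "umi",
]

_DUP_KEY = ["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2", "umi"]


@dataclass
class ContactMatrix:
    """Symmetric nonnegative contact matrix over (a retained subset of) a bin table.

    ``retained`` holds the genome-wide bin indices corresponding to matrix
    rows; for a raw matrix it is ``arange(n_bins)``. ``stage`` is one of
    ``raw``, ``filtered``, ``normalized``.
    """

    matrix: np.ndarray
    bins: BinTable
    retained: np.ndarray = field(default=None)  # type: ignore[assignment]
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("contact matrix must be square")
        if self.retained is None:
            self.retained = np.arange(len(self.bins))
        self.retained = np.asarray(self.retained, dtype=np.int64)
        if len(self.retained) != self.matrix.shape[0]:
            raise ValueError("retained index length must match matrix size")
        if np.any(self.matrix < 0):
            raise ValueError("contact matrix must be nonnegative")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def retained_chroms(self) -> np.ndarray:
        return self.bins.chrom[self.retained]

    def row_of_bin(self) -> dict[int, int]:
        """Genome-wide bin id -> matrix row."""
        return {int(b): i for i, b in enumerate(self.retained)}

    def is_symmetric(self, tol: float = 1e-9) -> bool:
        return bool(np.allclose(self.matrix, self.matrix.T, atol=tol))


@dataclass(frozen=True)
class PreprocessStats:
    n_input: int
    n_lowq_removed: int
    n_duplicates_collapsed: int
    n_output: int


def preprocess_pairs(pairs: pd.DataFrame, mapq_min: int = 40) -> tuple[pd.DataFrame, PreprocessStats]:
    """Remove low-quality pairs and collapse PCR duplicates.

    A pair is kept only if *both* mates have mapping quality strictly greater
    than ``mapq_min`` (default 40). Duplicates — identical in both mates'
    coordinates, both strands and the 6-nt tag — collapse to one
    representative. Without a ``umi`` column, collapse falls back to
    coordinates and strands alone (warning).
    """
    n_input = len(pairs)
    good = (pairs["mapq1"] > mapq_min) & (pairs["mapq2"] > mapq_min)
    kept = pairs.loc[good]
    n_lowq = n_input - len(kept)
    if "umi" in kept.columns:
        key = _DUP_KEY
    else:
        warnings.warn("no 'umi' column: collapsing duplicates on coordinates alone")
        key = [k for k in _DUP_KEY if k != "umi"]
    out = kept.drop_duplicates(subset=key, keep="first").reset_index(drop=True)
    stats = PreprocessStats(n_input, n_lowq, len(kept) - len(out), len(out))
    return out, stats


def build_contact_matrix(
    pairs: pd.DataFrame,
    frag_map: RestrictionFragmentMap,
    bins: BinTable,
) -> tuple[ContactMatrix, int]:
    """Aggregate preprocessed pairs into a raw genome-wide count matrix.

    Each mate is assigned to the restriction fragment whose half-open
    interval contains its position, fragments map to bins, and each pair
    increments the unordered bin pair (symmetrically off-diagonal, once on
    the diagonal). Returns the raw matrix and the number of rejected records
    (mate outside any fragment or on an unknown chromosome).
    """
    n = len(bins)
    M = np.zeros((n, n))
    n_rejected = 0
    known = set(frag_map.chrom_order)
    for (c1, c2), grp in pairs.groupby(["chrom1", "chrom2"], sort=False):
        if c1 not in known or c2 not in known:
            n_rejected += len(grp)
            continue
        f1 = frag_map.locate(c1, grp["pos1"].to_numpy())
        f2 = frag_map.locate(c2, grp["pos2"].to_numpy())
        b1 = bins.bin_of_fragment(c1, f1)
        b2 = bins.bin_of_fragment(c2, f2)
        ok = (b1 >= 0) & (b2 >= 0)
        n_rejected += int((~ok).sum())
        b1, b2 = b1[ok], b2[ok]
        np.add.at(M, (b1, b2), 1.0)
        off = b1 != b2
        np.add.at(M, (b2[off], b1[off]), 1.0)
    return ContactMatrix(M, bins, stage="raw"), n_rejected


def filter_bins(M: ContactMatrix, min_coverage_quantile: float = 0.01) -> ContactMatrix:
    """Mask zero-coverage bins and bins below a quantile of nonzero marginals.

    The matrix is restricted to retained bins; the retained genome-wide bin
    indices are recorded on the result. Raises if everything would be masked.
    """
    marg = M.matrix.sum(axis=0)
    nonzero = marg[marg > 0]
    if nonzero.size == 0:
        raise ValueError("all bins have zero coverage; nothing to retain")
    thresh = np.quantile(nonzero, min_coverage_quantile)
    keep = marg >= thresh
    keep &= marg > 0
    if not keep.any():
        raise ValueError("coverage filter masked every bin")
    idx = np.flatnonzero(keep)
    sub = M.matrix[np.ix_(idx, idx)]
    return ContactMatrix(sub, M.bins, retained=M.retained[idx], stage="filtered")


def scn_normalize(M: ContactMatrix, tol: float = 1e-6, max_iter: int = 200) -> ContactMatrix:
    """Sequential component normalization: iterate column normalization, row
    normalization and symmetrization until the matrix is doubly stochastic.

    Stops when every row and column sum is within ``tol`` of 1; raises with
    the residual if ``max_iter`` rounds do not converge. Symmetry and the
    off-mask zero pattern are preserved.
    """
    A = M.matrix.astype(float).copy()
    col = A.sum(axis=0)
    row = A.sum(axis=1)
    if np.any(col == 0) or np.any(row == 0):
        raise ValueError("zero rows/columns present; run filter_bins first")
    resid = np.inf
    for _ in range(max_iter):
        A = A / A.sum(axis=0, keepdims=True)
        A = A / A.sum(axis=1, keepdims=True)
        A = 0.5 * (A + A.T)
        resid = max(
            np.abs(A.sum(axis=0) - 1.0).max(),
            np.abs(A.sum(axis=1) - 1.0).max(),
        )
        if resid < tol:
            break
    else:
        raise RuntimeError(f"SCN did not converge in {max_iter} iterations (residual {resid:.3e})")
    return replace(M, matrix=A, stage="normalized")


# --- I/O ---------------------------------------------------------------

def write_pairs(pairs: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(PAIR_COLUMNS) + "\n")
        pairs.to_csv(fh, sep="\t", header=False, index=False, columns=PAIR_COLUMNS)


def read_pairs(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=PAIR_COLUMNS,
                     dtype={"chrom1": str, "chrom2": str, "umi": str})
    return df


def write_matrix_tsv(M: ContactMatrix, path) -> None:
    """Dense tab-separated matrix with genome-wide bin ids as headers."""
    ids = [str(int(b)) for b in M.retained]
    df = pd.DataFrame(M.matrix, index=ids, columns=ids)
    df.to_csv(path, sep="\t", index_label="bin")


def read_matrix_tsv(path, bins: BinTable, stage: str = "raw") -> ContactMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    retained = np.asarray([int(c) for c in df.columns])
    return ContactMatrix(df.to_numpy(float), bins, retained=retained, stage=stage)


def write_matrix_mtx(M: ContactMatrix, path) -> None:
    scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(M.matrix))


def read_matrix_mtx(path, bins: BinTable, retained=None, stage: str = "raw") -> ContactMatrix:
    A = scipy.io.mmread(str(path)).toarray()
    return ContactMatrix(A, bins, retained=retained, stage=stage)
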