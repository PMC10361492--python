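"""Loading, validation and balancing of intra-chromosomal Hi-C contact matrices.

A contact matrix is a symmetric, nonnegative ``bins x bins`` count matrix at a
fixed genomic bin size (e.g. 100 kb).  Unmappable or unsequenced stretches
(centromeres, assembly gaps) show up as all-zero rows; they are tracked in a
per-bin validity mask and excluded from every downstream computation.

Balancing removes coverage biases by finding a diagonal rescaling
``W_ij = x_i * x_j * A_ij`` whose valid rows all sum to one (Knight-Ruiz /
doubly-stochastic scaling restricted to the valid submatrix).  Equal row sums
make the modularity resolution parameter comparable across chromosomes of
different lengths and sequencing depths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ContactMatrix",
    "BalancingResult",
    "load_contact_matrix",
    "kr_balance",
    "fit_decay_exponent",
]

#: fraction of nonzero row sums below which a bin is masked before balancing
LOW_COVERAGE_PERCENTILE = 5.0

_SYM_TOL = 1e-9


@dataclass
class ContactMatrix:
    """Symmetric nonnegative contact-count matrix for one chromosome.

    Parameters
    ----------
    counts
        ``n x n`` nonnegative float array.  Symmetrized and diagonal-zeroed
        on construction (self-contacts never enter the modularity sum).
    bin_size
        Genomic span of one bin in base pairs.
    chrom
        Chromosome label, e.g. ``"chr10"``.
    valid_mask
        Boolean per-bin mask; ``False`` marks unmappable/all-zero bins.
        Computed from all-zero rows when not given.
    """

    counts: np.ndarray
    bin_size: int = 100_000
    chrom: str = "chrN"
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError(f"counts must be square, got shape {c.shape}")
        if np.any(c < 0):
            raise ValueError("contact counts must be nonnegative")
        asym = np.abs(c - c.T).max(initial=0.0)
        if asym > _SYM_TOL * max(1.0, np.abs(c).max(initial=0.0)):
            warnings.warn(
                f"matrix asymmetric (max deviation {asym:.3g}); symmetrizing",
                stacklevel=2,
            )
        c = 0.5 * (c + c.T)
        np.fill_diagonal(c, 0.0)
        self.counts = c
        if self.valid_mask is None:
            self.valid_mask = c.sum(axis=1) > 0
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool).copy()
            self.valid_mask &= c.sum(axis=1) > 0
        if self.valid_mask.shape != (c.shape[0],):
            raise ValueError("valid_mask length must match matrix size")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def valid_submatrix(self) -> np.ndarray:
        """Counts restricted to valid bins (copy)."""
        m = self.valid_mask
        return self.counts[np.ix_(m, m)].copy()


@dataclass
class BalancingResult:
    """Outcome of matrix balancing.

    ``scaled.counts[i, j] == scale_vector[i] * scale_vector[j] * counts[i, j]``
    on valid bins, with every valid row of ``scaled.counts`` summing to 1
    within the requested tolerance.  ``scale_vector`` is NaN on masked bins.
    """

    scaled: ContactMatrix
    scale_vector: np.ndarray
    converged: bool
    iterations: int


def _read_dense_tsv(path: Path, skip_header: bool) -> np.ndarray:
    try:
        if skip_header:
            import pandas as pd

            df = pd.read_csv(path, sep="\t", index_col=0)
            arr = df.to_numpy(dtype=float)
        else:
            arr = np.loadtxt(path, dtype=float, ndmin=2)
    except Exception as exc:  # noqa: BLE001 - wrap any parser failure
        raise ValueError(f"could not parse {path} as dense-tsv: {exc}") from exc
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError(f"dense matrix in {path} is not square: shape {arr.shape}")
    return arr


def _read_coo_text(path: Path) -> np.ndarray:
    try:
        trip = np.loadtxt(path, dtype=float, ndmin=2)
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"could not parse {path} as coo-text: {exc}") from exc
    if trip.size == 0:
        raise ValueError(f"{path}: empty coo-text file")
    if trip.shape[1] != 3:
        raise ValueError(f"{path}: coo-text needs 3 columns, got {trip.shape[1]}")
    i = trip[:, 0].astype(int)
    j = trip[:, 1].astype(int)
    v = trip[:, 2]
    if np.any(i < 0) or np.any(j < 0):
        raise ValueError("coo-text bin indices must be nonnegative")
    n = int(max(i.max(), j.max())) + 1
    a = np.zeros((n, n))
    # mirror across the diagonal: upper- or lower-triangle input both accepted
    a[i, j] = v
    a[j, i] = v
    return a


def _read_cooler(path: Path, chrom: str) -> tuple[np.ndarray, int]:
    """Read raw counts for one chromosome from a single-resolution cooler file.

    Walks the standard cooler HDF5 layout (``chroms``, ``bins``, ``pixels``)
    directly; only intra-chromosomal pixels of the requested chromosome are
    materialized.
    """
    import h5py

    with h5py.File(path, "r") as f:
        grp = f
        if "pixels" not in grp:  # multi-cooler container: take first group
            raise ValueError(f"{path}: not a single-resolution cooler file")
        names = [n.decode() if isinstance(n, bytes) else n for n in grp["chroms/name"][:]]
        if chrom not in names:
            raise KeyError(f"chromosome {chrom!r} not in {path} (has {names})")
        bin_chrom = grp["bins/chrom"][:]
        bin_start = grp["bins/start"][:]
        bin_end = grp["bins/end"][:]
        cid = names.index(chrom)
        sel = np.flatnonzero(bin_chrom == cid)
        lo, hi = int(sel[0]), int(sel[-1]) + 1
        bin_size = int(np.median(bin_end[sel] - bin_start[sel]))
        b1 = grp["pixels/bin1_id"][:]
        b2 = grp["pixels/bin2_id"][:]
        cnt = grp["pixels/count"][:].astype(float)
        keep = (b1 >= lo) & (b1 < hi) & (b2 >= lo) & (b2 < hi)
        n = hi - lo
        a = np.zeros((n, n))
        a[b1[keep] - lo, b2[keep] - lo] = cnt[keep]
        a[b2[keep] - lo, b1[keep] - lo] = cnt[keep]
    return a, bin_size


def load_contact_matrix(
    path: str | Path,
    format: str = "dense-tsv",
    chrom: str = "chrN",
    bin_size: int = 100_000,
    skip_header: bool = False,
) -> ContactMatrix:
    """Load an intra-chromosomal contact matrix from disk.

    Parameters
    ----------
    path
        Input file.
    format
        One of ``"dense-tsv"`` (tab-separated square matrix), ``"coo-text"``
        (whitespace-separated ``bin_i bin_j count`` triples, 0-based, mirrored
        across the diagonal on load) or ``"cooler-container"`` (single-
        resolution cooler HDF5; raw counts).
    chrom
        Chromosome label; selects the chromosome for cooler input.
    bin_size
        Bin size in bp for text dialects (cooler carries its own).
    skip_header
        For dense-tsv: ignore a leading header row and index column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "dense-tsv":
        arr = _read_dense_tsv(path, skip_header)
    elif format == "coo-text":
        arr = _read_coo_text(path)
    elif format == "cooler-container":
        arr, bin_size = _read_cooler(path, chrom)
    else:
        raise ValueError(f"unknown format {format!r}")
    return ContactMatrix(arr, bin_size=bin_size, chrom=chrom)


def mask_low_coverage(m: ContactMatrix, percentile: float = LOW_COVERAGE_PERCENTILE) -> ContactMatrix:
    """Additionally mask bins whose row sum falls below the given percentile
    of nonzero row sums (standard Hi-C practice; protects balancing)."""
    rs = m.counts.sum(axis=1)
    nz = rs[rs > 0]
    if nz.size == 0:
        return m
    thr = np.percentile(nz, percentile)
    mask = m.valid_mask & (rs >= thr)
    return ContactMatrix(m.counts, bin_size=m.bin_size, chrom=m.chrom, valid_mask=mask)


def kr_balance(
    m: ContactMatrix,
    tol: float = 1e-6,
    max_iter: int = 3000,
    mask_low: bool = False,
) -> BalancingResult:
    """Balance a contact matrix so every valid row sums to 1.

    Uses the symmetric Sinkhorn fixed-point iteration
    ``x <- x / sqrt(x * (A @ x))`` on the valid submatrix, which converges to
    the same diagonal scaling as Knight-Ruiz for symmetric nonnegative
    matrices with total support.

    Parameters
    ----------
    m
        Input matrix; masked bins are left untouched (zero rows/cols).
    tol
        Maximum allowed deviation of valid row sums from 1.
    max_iter
        Iteration cap; if reached, a warning is issued and the partial
        result returned with ``converged=False``.
    mask_low
        Apply the low-coverage percentile filter before balancing.
    """
    if mask_low:
        m = mask_low_coverage(m)
    if m.n_valid == 0:
        raise ValueError("no valid bins to balance")
    if m.n_valid < 2:
        raise ValueError("need at least 2 valid bins to balance")
    a = m.valid_submatrix()
    n = a.shape[0]
    x = np.ones(n)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        s = x * (a @ x)  # current row sums of diag(x) A diag(x)
        if np.max(np.abs(s - 1.0)) < tol:
            converged = True
            break
        if np.any(s <= 0):
            raise ValueError("matrix has an effectively zero row among valid bins; mask it first")
        x = x / np.sqrt(s)
    else:
        warnings.warn(
            f"kr_balance did not reach tol={tol} in {max_iter} iterations",
            stacklevel=2,
        )
    scaled_sub = (x[:, None] * a) * x[None, :]
    full = np.zeros_like(m.counts)
    idx = np.flatnonzero(m.valid_mask)
    full[np.ix_(idx, idx)] = scaled_sub
    scale_vector = np.full(m.n_bins, np.nan)
    scale_vector[idx] = x
    scaled = ContactMatrix(full, bin_size=m.bin_size, chrom=m.chrom, valid_mask=m.valid_mask)
    return BalancingResult(scaled=scaled, scale_vector=scale_vector, converged=converged, iterations=it)


def fit_decay_exponent(m: ContactMatrix, min_sep: int = 1, max_sep: int | None = None) -> float:
    """Estimate the contact-decay exponent alpha from mean count vs distance.

    Fits a least-squares line to ``log(mean count at separation s)`` against
    ``log s`` over valid bin pairs and returns ``-slope`` (so a fractal-
    globule matrix returns approximately 1).
    """
    n = m.n_bins
    if max_sep is None:
        max_sep = n // 2
    seps, means = [], []
    valid = m.valid_mask
    for s in range(min_sep, max_sep + 1):
        i = np.arange(0, n - s)
        keep = valid[i] & valid[i + s]
        if keep.sum() == 0:
            continue
        mu = m.counts[i[keep], i[keep] + s].mean()
        if mu > 0:
            seps.append(s)
            means.append(mu)
    if len(seps) < 2:
        raise ValueError("not enough separations with signal to fit a decay exponent")
    slope = np.polyfit(np.log(np.asarray(seps, float)), np.log(np.asarray(means)), 1)[0]
    return -float(slope)
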