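"""Loop-strength quantification on balanced Hi-C contact matrices.

A binned contact matrix carries multiplicative per-bin biases (coverage,
GC, mappability).  Matrix balancing removes them by finding diagonal weights
w such that diag(w) * M * diag(w) has equal row sums (Knight-Ruiz style
scaling); strengths measured on the balanced matrix are then comparable
across loci.  A chromatin loop, given as a BEDPE anchor pair, is quantified
as the mean balanced contact over the anchor1 x anchor2 block after
extending each anchor by two bins (at the default 5 kb resolution) on both
sides; loops are ranked by the percentile of their strength among all loops.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .genomics import Convention, GenomicInterval, ParseError

__all__ = [
    "ContactMatrix",
    "Loop",
    "BalanceError",
    "kr_balance",
    "loop_strength",
    "percentile_rank",
    "strength_histogram",
    "log_view",
    "read_bedpe",
    "read_matrix_dense",
    "read_matrix_coo",
    "read_matrix",
]

DEFAULT_BIN_SIZE = 5000
DEFAULT_EXTEND_BINS = 2


class BalanceError(RuntimeError):
    """Balancing failed to converge; carries the final row-sum residual."""

    def __init__(self, residual: float, iterations: int):
        self.residual = residual
        self.iterations = iterations
        super().__init__(
            f"matrix balancing did not converge after {iterations} iterations "
            f"(residual {residual:.3e})"
        )


@dataclass
class ContactMatrix:
    """Symmetric binned contact matrix for one chromosome.

    ``weights`` (set by :func:`kr_balance`) are NaN on masked bins (zero raw
    marginals); ``balanced`` is the bias-corrected matrix with masked rows
    and columns NaN.
    """

    chrom: str
    counts: np.ndarray
    bin_size: int = DEFAULT_BIN_SIZE
    weights: Optional[np.ndarray] = None

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.allclose(c, c.T, atol=1e-9):
            raise ValueError("contact matrix must be symmetric")
        if (c < 0).any():
            raise ValueError("contact matrix must be nonnegative")
        self.counts = c

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def balanced(self) -> np.ndarray:
        if self.weights is None:
            raise ValueError("matrix not balanced yet; call kr_balance first")
        w = self.weights
        out = self.counts * np.outer(w, w)
        mask = np.isnan(w)
        out[mask, :] = np.nan
        out[:, mask] = np.nan
        return out

    def bin_range(self, iv: GenomicInterval) -> tuple[int, int]:
        """Bins covering the interval (floor/ceil to full bins), half-open."""
        half = iv.to_half_open()
        if half.chrom != self.chrom:
            raise ValueError(f"interval on {half.chrom}, matrix is {self.chrom}")
        lo = half.start // self.bin_size
        hi = -(-half.end // self.bin_size)  # ceil division
        if hi > self.n_bins:
            raise ValueError(
                f"interval {half.chrom}:{half.start}-{half.end} extends beyond "
                f"the {self.n_bins}-bin matrix"
            )
        return lo, hi


def kr_balance(matrix: ContactMatrix, tol: float = 1e-8,
               max_iter: int = 1000) -> tuple[ContactMatrix, np.ndarray]:
    """Balance a symmetric contact matrix so unmasked row sums equalize.

    Rows with zero raw sum are masked (NaN weight) and excluded from the
    criterion.  The iteration updates w <- w / sqrt(rowsum ratio) — the
    symmetric fixed point of Knight-Ruiz scaling — until every unmasked row
    sum of diag(w) M diag(w) equals the mean row sum within ``tol``
    (relative).  Row sums are normalised to their mean, so strengths are
    comparable across runs; the iteration count is recorded on the result.
    """
    M = matrix.counts
    n = M.shape[0]
    active = M.sum(axis=1) > 0
    w = np.ones(n)
    w[~active] = np.nan
    Ma = M[np.ix_(active, active)]
    wa = np.ones(active.sum())
    residual = np.inf
    for it in range(1, max_iter + 1):
        rowsums = (Ma * np.outer(wa, wa)).sum(axis=1)
        mean = rowsums.mean()
        ratio = rowsums / mean
        residual = float(np.abs(ratio - 1).max())
        if residual < tol:
            break
        wa = wa / np.sqrt(ratio)
    else:
        raise BalanceError(residual, max_iter)
    # scale so unmasked row sums equal their mean under the raw-count scale
    w[active] = wa
    out = ContactMatrix(matrix.chrom, matrix.counts, matrix.bin_size, weights=w)
    out.iterations = it
    return out, w


def loop_strength(matrix: ContactMatrix, loop: "Loop",
                  extend_bins: int = DEFAULT_EXTEND_BINS) -> float:
    """Mean balanced contact over the extended anchor1 x anchor2 block.

    Each anchor's covering bin range is extended by ``extend_bins`` on both
    sides (clipped at the matrix edge); masked bins are excluded from both
    numerator and denominator.  Returns NaN when the whole block is masked.
    """
    bal = matrix.balanced
    (a_lo, a_hi), (b_lo, b_hi) = (matrix.bin_range(loop.anchor1),
                                  matrix.bin_range(loop.anchor2))
    a_lo = max(0, a_lo - extend_bins)
    a_hi = min(matrix.n_bins, a_hi + extend_bins)
    b_lo = max(0, b_lo - extend_bins)
    b_hi = min(matrix.n_bins, b_hi + extend_bins)
    block = bal[a_lo:a_hi, b_lo:b_hi]
    if np.isnan(block).all():
        return float("nan")
    return float(np.nanmean(block))


@dataclass
class Loop:
    anchor1: GenomicInterval
    anchor2: GenomicInterval
    strength: Optional[float] = None
    percentile: Optional[float] = None

    def __post_init__(self):
        if self.anchor1.chrom != self.anchor2.chrom:
            raise ValueError("interchromosomal loops are not supported")


def percentile_rank(value: float, all_strengths: Sequence[float]) -> int:
    """Inclusive percentile: 100 * #(strengths <= value) / N, nearest integer."""
    arr = np.asarray(all_strengths, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("percentile_rank of empty strength list")
    pct = 100.0 * float((arr <= value).sum()) / arr.size
    return int(math.floor(pct + 0.5))


def strength_histogram(strengths: Sequence[float],
                       n_bins: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of loop strengths; counts sum to the number of loops."""
    arr = np.asarray(strengths, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("strengths must be finite")
    return np.histogram(arr, bins=n_bins)


def log_view(matrix: np.ndarray) -> np.ndarray:
    """log(1+x) transform for display of contact matrices."""
    return np.log1p(matrix)


def read_bedpe(path: Union[str, Path]) -> list[Loop]:
    """BEDPE loops with 0-based half-open anchors."""
    loops = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"BEDPE record has {len(parts)} fields, need >=6",
                                 line=i)
            try:
                a = GenomicInterval(parts[0], int(parts[1]), int(parts[2]),
                                    Convention.ZERO_BASED_HALF_OPEN)
                b = GenomicInterval(parts[3], int(parts[4]), int(parts[5]),
                                    Convention.ZERO_BASED_HALF_OPEN)
            except ValueError as e:
                raise ParseError(str(e), line=i) from None
            loops.append(Loop(a, b))
    return loops


def read_matrix_dense(path: Union[str, Path], chrom: str = "chr1",
                      bin_size: int = DEFAULT_BIN_SIZE) -> ContactMatrix:
    """Dense whitespace-separated square matrix."""
    arr = np.loadtxt(path, dtype=float)
    if arr.ndim == 0:
        arr = arr.reshape(1, 1)
    return ContactMatrix(chrom, arr, bin_size)


def read_matrix_coo(path: Union[str, Path], chrom: str = "chr1",
                    bin_size: int = DEFAULT_BIN_SIZE,
                    n_bins: Optional[int] = None) -> ContactMatrix:
    """COO triplets (bin_i, bin_j, count); symmetric fill from either triangle."""
    rows, cols, vals = [], [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ParseError(f"COO record has {len(parts)} fields, need 3", line=ln)
            try:
                i, j, v = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError as e:
                raise ParseError(str(e), line=ln) from None
            rows.append(i)
            cols.append(j)
            vals.append(v)
    if not rows:
        raise ParseError(f"no records in {path}")
    n = n_bins or (max(max(rows), max(cols)) + 1)
    M = np.zeros((n, n))
    for i, j, v in zip(rows, cols, vals):
        M[i, j] = v
        M[j, i] = v
    return ContactMatrix(chrom, M, bin_size)


def read_matrix(path: Union[str, Path], chrom: str = "chr1",
                bin_size: int = DEFAULT_BIN_SIZE) -> ContactMatrix:
    """Auto-detect dense vs COO text layout."""
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ncols = len(line.split())
                break
        else:
            raise ParseError(f"empty matrix file {path}")
    if ncols == 3:
        return read_matrix_coo(path, chrom, bin_size)
    return read_matrix_dense(path, chrom, bin_size)
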