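"""All-pairs Pearson correlation in packed triangular storage.

For k genes there are t = k(k-1)/2 distinct pairs. Only the strictly
lower triangle of the symmetric correlation matrix is stored, as a flat
vector in row-major order: (1,0), (2,0), (2,1), (3,0), ... with 0-based
gene indices, so pair (i, j) with j < i lives at slot i(i-1)/2 + j.

The coefficients are computed by blocked matrix products over
mean-centered, unit-norm gene rows — algebraically identical to the
one-pass sums-of-products form of the Pearson coefficient but
numerically stable for large means, and O(n k^2) through BLAS rather
than a per-pair Python loop.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix

__all__ = [
    "PackedTriangular",
    "pair_to_index",
    "index_to_pair",
    "pearson_all_pairs",
]

logger = logging.getLogger(__name__)


@dataclass
class PackedTriangular:
    """Flat vector of the k(k-1)/2 strictly-lower-triangular pair values."""

    k: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        t = self.k * (self.k - 1) // 2
        if self.values.shape != (t,):
            raise ValueError(
                f"packed vector for k={self.k} must have length {t}, "
                f"got {self.values.shape}"
            )

    @property
    def n_pairs(self) -> int:
        return len(self.values)

    def to_square(self, diagonal: float = 1.0) -> np.ndarray:
        """Unpack to a full symmetric k x k matrix."""
        mat = np.full((self.k, self.k), diagonal, dtype=np.float64)
        rows, cols = np.tril_indices(self.k, -1)
        mat[rows, cols] = self.values
        mat[cols, rows] = self.values
        return mat


def pair_to_index(i: int, j: int) -> int:
    """Packed slot of gene pair (i, j), requiring 0 <= j < i."""
    if not 0 <= j < i:
        raise ValueError(
            f"pair ({i}, {j}) is not in the strictly lower triangle (need 0 <= j < i)"
        )
    return i * (i - 1) // 2 + j


def index_to_pair(idx: int, k: int) -> tuple[int, int]:
    """Gene pair (i, j) stored at packed slot `idx`; exact inverse of
    :func:`pair_to_index`."""
    t = k * (k - 1) // 2
    if not 0 <= idx < t:
        raise ValueError(f"packed index {idx} out of range [0, {t}) for k={k}")
    # integer sqrt keeps the inversion exact for all representable t
    i = (1 + math.isqrt(1 + 8 * idx)) // 2
    j = idx - i * (i - 1) // 2
    return i, j


def _standardized_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center each row and scale to unit Euclidean norm.

    Zero-variance rows (constant genes, including all-zero rows passed
    through the entropy filter) are mapped to zero vectors so every
    correlation involving them is exactly 0.
    """
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered * centered).sum(axis=1))
    degenerate = norms == 0.0
    norms[degenerate] = 1.0
    return centered / norms[:, None], degenerate


def pearson_all_pairs(
    expr: ExpressionMatrix, block_size: int = 2048
) -> PackedTriangular:
    """Pearson correlation for every gene pair, packed lower-triangular.

    Constant (zero-variance) genes yield rho = 0 for all their pairs; a
    warning names them. Computation proceeds in row blocks of
    `block_size` genes so peak memory stays near
    ``block_size * k`` doubles on top of the packed result.

    Raises
    ------
    ValueError
        If there are fewer than 2 genes or fewer than 3 samples.
    """
    k, n = expr.n_genes, expr.n_samples
    if k < 2:
        raise ValueError("correlation requires at least 2 genes")
    if n < 3:
        raise ValueError("correlation requires at least 3 samples")
    if block_size < 1:
        raise ValueError("block_size must be positive")

    standardized, degenerate = _standardized_rows(expr.values)
    if degenerate.any():
        names = [expr.gene_ids[i] for i in np.flatnonzero(degenerate)]
        logger.warning(
            "%d zero-variance gene(s) — correlations set to 0: %s",
            len(names),
            ", ".join(names[:10]) + ("..." if len(names) > 10 else ""),
        )

    t = k * (k - 1) // 2
    out = np.empty(t, dtype=np.float64)
    for start in range(1, k, block_size):
        stop = min(start + block_size, k)
        # correlations of rows [start, stop) against all earlier rows
        block = standardized[start:stop] @ standardized[:stop].T
        for local, i in enumerate(range(start, stop)):
            base = i * (i - 1) // 2
            out[base : base + i] = block[local, :i]
    np.clip(out, -1.0, 1.0, out=out)
    return PackedTriangular(k=k, values=out)
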