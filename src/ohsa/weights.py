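"""Binary distance-band spatial weights between fishnet cell centroids.

w_ij = 1 iff centroid distance(i, j) <= d (inclusive) and i != j; the
diagonal is governed by ``include_self``.  Weights are binary and never
row-standardized: the global and local statistics downstream are their
binary-weight forms.  Moran's I uses include_self=False; the Gi* statistic
uses include_self=True (the "star" places the focal cell in its own
neighborhood).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

__all__ = ["WeightsMatrix", "distance_band_weights"]


@dataclass
class WeightsMatrix:
    """Sparse symmetric binary weights for one band distance."""

    d: float
    include_self: bool
    matrix: sp.csr_matrix  # n x n, entries in {0, 1}

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def row_sums(self) -> np.ndarray:
        """Per-row weight totals; equals row sums of squares for binary weights."""
        return np.asarray(self.matrix.sum(axis=1)).ravel()

    @property
    def s0(self) -> float:
        """S0: the sum of all spatial weights."""
        return float(self.matrix.sum())

    def to_edge_list(self, path) -> None:
        coo = self.matrix.tocoo()
        with open(path, "w") as fh:
            fh.write("i\tj\tw\n")
            for i, j, v in zip(coo.row, coo.col, coo.data):
                fh.write(f"{i}\t{j}\t{int(v)}\n")


def distance_band_weights(
    lattice_or_points, d: float, include_self: bool = False
) -> WeightsMatrix:
    """Build binary distance-band weights over lattice cell centroids.

    Accepts a CountLattice or an (n, 2) coordinate array.  Warns when every
    off-diagonal row is empty (Moran's I undefined at that band distance).
    """
    if d < 0:
        raise ValueError("band distance must be non-negative")
    pts = getattr(lattice_or_points, "centroids", lattice_or_points)
    pts = np.asarray(pts, float)
    n = len(pts)
    if n == 0:
        raise ValueError("no cells to build weights over")

    tree = cKDTree(pts)
    pairs = tree.query_pairs(d, output_type="ndarray") if d > 0 else np.empty((0, 2), int)
    if len(pairs):
        rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
        cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
    else:
        rows = np.empty(0, int)
        cols = np.empty(0, int)
    if include_self:
        rows = np.concatenate([rows, np.arange(n)])
        cols = np.concatenate([cols, np.arange(n)])
    mat = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n, n)
    )
    if len(pairs) == 0 and not include_self:
        warnings.warn(
            f"band distance {d} m yields no neighbors: Moran's I is undefined",
            stacklevel=2,
        )
    return WeightsMatrix(d=float(d), include_self=include_self, matrix=mat)
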