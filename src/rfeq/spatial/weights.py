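"""Spatial weight matrices for autocorrelation statistics.

Two schemes: k-nearest neighbors (default k = 8, ties broken by index
order, so construction is deterministic) and a fixed distance band
(symmetric, closed at the band distance). Weights are binary before row
standardization; row-standardized rows sum to one. Self-weights are always
zero, and isolated units are not permitted — Moran/LISA inference is
undefined for a unit with no neighbors, so a distance band that strands a
point raises with a suggestion to widen the band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import sparse
from scipy.spatial.distance import cdist

__all__ = ["SpatialWeights", "build_weights"]


@dataclass(frozen=True)
class SpatialWeights:
    """Neighbor lists with weights; convertible to a sparse CSR matrix."""

    scheme: str
    parameter: float
    row_standardized: bool
    neighbors: tuple[tuple[int, ...], ...]
    weights: tuple[tuple[float, ...], ...]

    @property
    def n(self) -> int:
        return len(self.neighbors)

    @property
    def cardinalities(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbors])

    @property
    def s0(self) -> float:
        """Sum of all weights."""
        return float(sum(sum(w) for w in self.weights))

    def to_sparse(self) -> sparse.csr_matrix:
        rows = np.repeat(np.arange(self.n), self.cardinalities)
        cols = np.concatenate([np.asarray(nb, dtype=int) for nb in self.neighbors])
        vals = np.concatenate([np.asarray(w, dtype=float) for w in self.weights])
        return sparse.csr_matrix((vals, (rows, cols)), shape=(self.n, self.n))

    def to_dense(self) -> np.ndarray:
        return self.to_sparse().toarray()

    def lag(self, values: np.ndarray) -> np.ndarray:
        """Spatial lag W @ values."""
        return self.to_sparse() @ np.asarray(values, dtype=float)


def build_weights(
    points: np.ndarray,
    scheme: str = "k_nearest",
    parameter: float = 8,
    row_standardize: bool = True,
) -> SpatialWeights:
    """Build k-nearest or distance-band weights from planar points."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    d = cdist(pts, pts)

    if scheme == "k_nearest":
        k = int(parameter)
        if not (1 <= k < n):
            raise ValueError(f"k must satisfy 1 <= k < n = {n}, got {k}")
        neighbors = []
        idx = np.arange(n)
        for i in range(n):
            order = np.lexsort((idx, d[i]))  # distance, then index: stable ties
            nb = [j for j in order if j != i][:k]
            neighbors.append(tuple(int(j) for j in nb))
    elif scheme == "distance_band":
        band = float(parameter)
        if band <= 0:
            raise ValueError(f"band distance must be positive, got {band}")
        neighbors = []
        for i in range(n):
            nb = np.flatnonzero((d[i] <= band) & (np.arange(n) != i))
            if nb.size == 0:
                raise ValueError(
                    f"unit {i} has no neighbor within {band}; increase the "
                    f"band distance (minimum pairwise distance is "
                    f"{_min_offdiag(d):.6g})"
                )
            neighbors.append(tuple(int(j) for j in nb))
    else:
        raise ValueError(
            f"unknown scheme {scheme!r}; use 'k_nearest' or 'distance_band'"
        )

    weights = []
    for nb in neighbors:
        if row_standardize:
            weights.append(tuple([1.0 / len(nb)] * len(nb)))
        else:
            weights.append(tuple([1.0] * len(nb)))
    return SpatialWeights(
        scheme=scheme,
        parameter=float(parameter),
        row_standardized=row_standardize,
        neighbors=tuple(neighbors),
        weights=tuple(weights),
    )


def _min_offdiag(d: np.ndarray) -> float:
    m = d + np.diag(np.full(len(d), np.inf))
    return float(m.min())
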