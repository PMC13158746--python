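"""Buffer-level re-scoring of the food environment around each outlet.

A retail neighborhood is the set of outlets within a metric radius of a
focal outlet, the focal outlet included. Presence of each food group is
pooled across the neighborhood by logical union ("does anybody within r
meters stock it?") and the three indices are recomputed on the pooled
presence. Default radii are 50, 100 and 200 m.

Conventions: closed-ball inclusion (distance <= r), so the focal outlet at
distance zero is always its own neighbor; buffers are not clipped at the
study-window boundary (an outlet near the edge simply pools the outlets
that exist).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .catalog import FoodGroupCatalog, default_catalog
from .indices import score_frame
from .io import RetailerRecord, records_to_frame
from .projection import project_to_plane

__all__ = ["BufferSpec", "neighbors_within", "buffer_presence", "score_buffers"]

# Above this many points, pairwise distance matrices give way to a KD-tree.
_EXACT_PAIRWISE_LIMIT = 10_000


@dataclass(frozen=True)
class BufferSpec:
    """Buffer radii in meters, sorted ascending; the focal outlet is always
    part of its own neighborhood."""

    radii: tuple[float, ...] = (50.0, 100.0, 200.0)
    include_focal: bool = True

    def __post_init__(self) -> None:
        if len(self.radii) == 0:
            raise ValueError("at least one buffer radius is required")
        if any(r <= 0 for r in self.radii):
            raise ValueError(f"buffer radii must be positive, got {self.radii}")
        if list(self.radii) != sorted(self.radii):
            raise ValueError(f"buffer radii must be sorted ascending, got {self.radii}")
        if not self.include_focal:
            raise ValueError("the focal outlet is always included in its buffer")


def neighbors_within(
    points: np.ndarray, focal: int, radius: float
) -> set[int]:
    """Indices of all points within ``radius`` of point ``focal`` (closed
    ball, focal included)."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    if not (0 <= focal < n):
        raise IndexError(f"focal index {focal} out of range for {n} points")
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    d = np.hypot(*(points - points[focal]).T)
    return set(np.flatnonzero(d <= radius).tolist())


def buffer_presence(
    records: Sequence[RetailerRecord],
    neighbor_set: set[int] | Sequence[int],
    catalog: Optional[FoodGroupCatalog] = None,
) -> dict[str, bool]:
    """Pool presence over a neighbor set: present iff present at >= 1 outlet."""
    catalog = catalog or default_catalog()
    idx = sorted(set(neighbor_set))
    if not idx:
        raise ValueError("cannot pool presence over an empty neighbor set")
    pooled = {code: False for code in catalog.codes}
    for i in idx:
        pres = records[i].presence
        for code in catalog.codes:
            pooled[code] = pooled[code] or bool(pres[code])
    return pooled


def _neighbor_mask(points: np.ndarray, radius: float) -> np.ndarray:
    """Boolean (n, n) matrix: d_ij <= radius (closed ball)."""
    n = len(points)
    if n <= _EXACT_PAIRWISE_LIMIT:
        return cdist(points, points) <= radius
    tree = cKDTree(points)
    # tiny inflation guards the closed-ball boundary against fp rounding;
    # contract: identical result to the exact pairwise path
    pairs = tree.query_ball_tree(tree, radius * (1 + 1e-12))
    mask = np.zeros((n, n), dtype=bool)
    for i, js in enumerate(pairs):
        d = np.hypot(*(points[js] - points[i]).T)
        good = np.asarray(js)[d <= radius]
        mask[i, good] = True
    return mask


def score_buffers(
    records: Sequence[RetailerRecord],
    spec: Optional[BufferSpec] = None,
    catalog: Optional[FoodGroupCatalog] = None,
    points: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Score each outlet and its buffers at every radius.

    Returns the retailer table with hrfes/urfes/rfeqi (retailer level, the
    radius->0 limit) plus hrfes_r{r}/urfes_r{r}/rfeqi_r{r} per radius.
    """
    spec = spec or BufferSpec()
    catalog = catalog or default_catalog()
    frame = records_to_frame(records, catalog)
    out = score_frame(frame, catalog)
    if points is None:
        points = project_to_plane(records)
    points = np.asarray(points, dtype=float)
    if len(points) != len(records):
        raise ValueError("points and records must have equal length")

    h_codes = list(catalog.healthy_codes)
    u_codes = list(catalog.unhealthy_codes)
    pres = frame[h_codes + u_codes].to_numpy(dtype=bool)
    h_w = np.array([catalog[c].weight for c in h_codes])
    u_w = np.array([catalog[c].weight for c in u_codes])

    for r in spec.radii:
        mask = _neighbor_mask(points, float(r))
        pooled = mask @ pres  # int matrix; >0 means present somewhere in buffer
        pooled = pooled > 0
        tag = _radius_tag(r)
        h = pooled[:, : len(h_codes)].astype(int) @ h_w
        u = pooled[:, len(h_codes):].astype(int) @ u_w
        out[f"hrfes_{tag}"] = h
        out[f"urfes_{tag}"] = u
        out[f"rfeqi_{tag}"] = h - u + 9
    return out


def _radius_tag(r: float) -> str:
    return f"r{int(r)}" if float(r).is_integer() else f"r{r:g}"
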