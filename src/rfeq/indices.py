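"""Retail food environment quality indices.

Three integer indices summarize what an outlet (or a pooled neighborhood of
outlets) offers:

* HRFES (healthy score, 0-9): number of the nine healthy food groups
  present, each worth one point.
* URFES (unhealthy score, 0-9): weighted count of the eight unhealthy food
  groups present; processed meats contribute two points, every other group
  one, so the maximum is again nine.
* RFEQI (composite quality index, 0-18): HRFES - URFES + 9. The +9 offset
  keeps the index non-negative; 18 means full healthy variety and nothing
  unhealthy, 0 the reverse, and 9 is the balance point.

Presence is strictly binary; a missing flag is an error, never a silent
zero, since silent zeros would bias scores downward.
"""

from __future__ import annotations

from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import FoodGroupCatalog, default_catalog
from .io import RetailerRecord, records_to_frame

__all__ = [
    "IndexTriple",
    "compute_hrfes",
    "compute_urfes",
    "compute_rfeqi",
    "score_table",
    "score_frame",
    "INDEX_COLUMNS",
]

INDEX_COLUMNS = ("hrfes", "urfes", "rfeqi")


class IndexTriple(NamedTuple):
    hrfes: int
    urfes: int
    rfeqi: int


def _weighted_presence_sum(
    presence: Mapping[str, bool], groups, side: str
) -> int:
    total = 0
    for g in groups:
        if g.code not in presence:
            raise KeyError(
                f"presence mapping missing {side} food group {g.code!r}"
            )
        total += g.weight * int(bool(presence[g.code]))
    return total


def compute_hrfes(
    presence: Mapping[str, bool], catalog: Optional[FoodGroupCatalog] = None
) -> int:
    """Healthy score: count of healthy groups present (0-9)."""
    catalog = catalog or default_catalog()
    return _weighted_presence_sum(presence, catalog.healthy, "healthy")


def compute_urfes(
    presence: Mapping[str, bool], catalog: Optional[FoodGroupCatalog] = None
) -> int:
    """Unhealthy score: weighted count of unhealthy groups present (0-9);
    processed meats count double."""
    catalog = catalog or default_catalog()
    return _weighted_presence_sum(presence, catalog.unhealthy, "unhealthy")


def compute_rfeqi(hrfes: int, urfes: int) -> int:
    """Composite quality index: hrfes - urfes + 9, in [0, 18]."""
    if not (0 <= hrfes <= 9):
        raise ValueError(f"hrfes must be in [0, 9], got {hrfes}")
    if not (0 <= urfes <= 9):
        raise ValueError(f"urfes must be in [0, 9], got {urfes}")
    return hrfes - urfes + 9


def score_presence(
    presence: Mapping[str, bool], catalog: Optional[FoodGroupCatalog] = None
) -> IndexTriple:
    """Score one presence mapping into (hrfes, urfes, rfeqi)."""
    catalog = catalog or default_catalog()
    h = compute_hrfes(presence, catalog)
    u = compute_urfes(presence, catalog)
    return IndexTriple(h, u, compute_rfeqi(h, u))


def score_frame(
    frame: pd.DataFrame, catalog: Optional[FoodGroupCatalog] = None
) -> pd.DataFrame:
    """Append hrfes/urfes/rfeqi columns to a table with presence columns."""
    catalog = catalog or default_catalog()
    missing = [c for c in catalog.codes if c not in frame.columns]
    if missing:
        raise KeyError(f"table missing presence column(s) {missing}")
    out = frame.copy()
    h_codes = list(catalog.healthy_codes)
    u_codes = list(catalog.unhealthy_codes)
    h_w = np.array([catalog[c].weight for c in h_codes])
    u_w = np.array([catalog[c].weight for c in u_codes])
    pres = out[h_codes + u_codes].to_numpy()
    if not np.isin(pres, (0, 1)).all():
        raise ValueError("presence columns must be binary 0/1")
    out["hrfes"] = pres[:, : len(h_codes)].astype(int) @ h_w
    out["urfes"] = pres[:, len(h_codes):].astype(int) @ u_w
    out["rfeqi"] = out["hrfes"] - out["urfes"] + 9
    return out


def score_table(
    records: Sequence[RetailerRecord],
    catalog: Optional[FoodGroupCatalog] = None,
) -> pd.DataFrame:
    """Score a record list into a table with appended index columns.

    Record order is preserved; an empty record list yields an empty table.
    """
    catalog = catalog or default_catalog()
    frame = records_to_frame(records, catalog)
    return score_frame(frame, catalog)
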