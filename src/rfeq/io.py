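"""Retailer data model and file I/O.

One row per food retail outlet: WGS84 coordinates, a rural/urban stratum,
one of twelve retail typologies, the retailer gender category, the share of
shelf space occupied by food, and a binary presence flag per food group in
the scoring catalog. Tables travel as CSV (header row, one presence column
per group code) or as GeoJSON FeatureCollections of Point features with the
same attributes in ``properties``; the study window is a GeoJSON
Polygon/MultiPolygon.

Category levels are closed enumerations so that regression contrasts are
reproducible; an unknown level is a hard error listing the allowed values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import shapely
from shapely.geometry import mapping as shapely_mapping
from shapely.geometry import shape as shapely_shape

from .catalog import FoodGroupCatalog, default_catalog

__all__ = [
    "RetailerRecord",
    "StudyWindow",
    "ValidationError",
    "STRATA",
    "TYPOLOGIES",
    "GENDERS",
    "SHELF_SPACE_LEVELS",
    "read_retailers",
    "write_retailers",
    "read_window",
    "records_to_frame",
    "frame_to_records",
    "write_scored_table",
    "read_scored_table",
]


class ValidationError(ValueError):
    """Invalid retailer record or table."""


STRATA: tuple[str, ...] = ("rural", "urban")

# code -> display label; the twelve retail typologies.
TYPOLOGY_LABELS: dict[str, str] = {
    "butcher": "Butcher",
    "cereal_shop": "Cereal shop",
    "cooked_food_street": "Cooked food street retailers",
    "farmgate": "Farmgate sale",
    "home_based": "Home-based retailers",
    "kiosk": "Kiosk",
    "mobile": "Mobile retailers",
    "mom_and_pop": "Mom-and-pop shops",
    "modern_restaurant": "Modern restaurant",
    "stall_tabletop": "Stall/tabletop",
    "supermarket": "Supermarket",
    "wholesaler": "Wholesalers",
}
TYPOLOGIES: tuple[str, ...] = tuple(TYPOLOGY_LABELS)

GENDER_LABELS: dict[str, str] = {
    "female": "Female",
    "male": "Male",
    "mixed": "Mixed gender",
    "multiple_females": "Multiple females",
    "multiple_males": "Multiple males",
}
GENDERS: tuple[str, ...] = tuple(GENDER_LABELS)

# Ordered from all-food outlets down to mostly non-food outlets.
SHELF_SPACE_LABELS: dict[str, str] = {
    "food_100": "100% food space",
    "food_75_99": "Between 75% and 100%",
    "food_50_74": "Between 75% and 50%",
    "food_25_49": "Between 50% and 25%",
    "below_25": "Below 25%",
}
SHELF_SPACE_LEVELS: tuple[str, ...] = tuple(SHELF_SPACE_LABELS)

_TRUTHY = {"1", "true", "yes", "present"}
_FALSY = {"0", "false", "no", "absent"}


@dataclass(frozen=True)
class RetailerRecord:
    """One outlet: identity, location, covariates, and per-group presence."""

    id: str
    lon: float
    lat: float
    stratum: str
    typology: str
    gender: str
    shelf_space: str
    presence: Mapping[str, bool]

    def validate(self, catalog: FoodGroupCatalog) -> "RetailerRecord":
        if not (-180.0 <= self.lon <= 180.0):
            raise ValidationError(
                f"record {self.id!r}: lon {self.lon} outside [-180, 180]"
            )
        if not (-90.0 <= self.lat <= 90.0):
            raise ValidationError(
                f"record {self.id!r}: lat {self.lat} outside [-90, 90]"
            )
        _check_level(self.id, "stratum", self.stratum, STRATA)
        _check_level(self.id, "typology", self.typology, TYPOLOGIES)
        _check_level(self.id, "gender", self.gender, GENDERS)
        _check_level(self.id, "shelf_space", self.shelf_space, SHELF_SPACE_LEVELS)
        for code in catalog.codes:
            if code not in self.presence:
                raise ValidationError(
                    f"record {self.id!r}: missing presence flag for food "
                    f"group {code!r}"
                )
        return self


def _check_level(rid: str, name: str, value: str, allowed: Sequence[str]) -> None:
    if value not in allowed:
        raise ValidationError(
            f"record {rid!r}: unknown {name} {value!r}; allowed levels: "
            f"{list(allowed)}"
        )


@dataclass(frozen=True)
class StudyWindow:
    """Planar study boundary (meters) with a note on the projection used."""

    polygon: shapely.Geometry
    crs_note: str = "local ENU meters"

    def __post_init__(self) -> None:
        if self.polygon.geom_type not in ("Polygon", "MultiPolygon"):
            raise ValidationError(
                f"study window must be a Polygon/MultiPolygon, got "
                f"{self.polygon.geom_type}"
            )
        if not self.polygon.is_valid:
            raise ValidationError("study window polygon is not simple/valid")
        if self.polygon.area <= 0:
            raise ValidationError("study window has non-positive area")

    @property
    def area(self) -> float:
        return self.polygon.area

    @property
    def diameter(self) -> float:
        minx, miny, maxx, maxy = self.polygon.bounds
        return math.hypot(maxx - minx, maxy - miny)


def _coerce_flag(rid: str, code: str, value) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        if float(value) in (0.0, 1.0):
            return bool(value)
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValidationError(
        f"record {rid!r}: presence flag for {code!r} must be binary, "
        f"got {value!r}"
    )


_BASE_COLUMNS = ("id", "lon", "lat", "stratum", "typology", "gender", "shelf_space")


def _row_to_record(row: Mapping, catalog: FoodGroupCatalog) -> RetailerRecord:
    rid = str(row["id"])
    presence = {}
    for code in catalog.codes:
        if code not in row or row[code] is None or (
            isinstance(row[code], float) and math.isnan(row[code])
        ):
            raise ValidationError(
                f"record {rid!r}: missing presence column for food group "
                f"{code!r}"
            )
        presence[code] = _coerce_flag(rid, code, row[code])
    rec = RetailerRecord(
        id=rid,
        lon=float(row["lon"]),
        lat=float(row["lat"]),
        stratum=str(row["stratum"]),
        typology=str(row["typology"]),
        gender=str(row["gender"]),
        shelf_space=str(row["shelf_space"]),
        presence=presence,
    )
    return rec.validate(catalog)


def read_retailers(
    path: str | Path, catalog: Optional[FoodGroupCatalog] = None
) -> list[RetailerRecord]:
    """Read a retailer table from CSV or GeoJSON, validating every record.

    Row order is preserved and the number of records returned equals the
    number of rows read.
    """
    catalog = catalog or default_catalog()
    path = Path(path)
    if path.suffix.lower() in (".geojson", ".json"):
        return _read_geojson(path, catalog)
    frame = pd.read_csv(path)
    return frame_to_records(frame, catalog)


def _read_geojson(path: Path, catalog: FoodGroupCatalog) -> list[RetailerRecord]:
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValidationError(f"{path}: expected a GeoJSON FeatureCollection")
    records = []
    for i, feat in enumerate(gj.get("features", [])):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Point":
            raise ValidationError(f"{path}: feature {i} is not a Point")
        lon, lat = geom["coordinates"][:2]
        props = dict(feat.get("properties") or {})
        props.setdefault("id", str(i))
        props["lon"], props["lat"] = lon, lat
        records.append(_row_to_record(props, catalog))
    return records


def records_to_frame(
    records: Iterable[RetailerRecord], catalog: Optional[FoodGroupCatalog] = None
) -> pd.DataFrame:
    """Tabulate records: base columns then one 0/1 column per group code."""
    catalog = catalog or default_catalog()
    rows = []
    for r in records:
        row = {
            "id": r.id,
            "lon": r.lon,
            "lat": r.lat,
            "stratum": r.stratum,
            "typology": r.typology,
            "gender": r.gender,
            "shelf_space": r.shelf_space,
        }
        for code in catalog.codes:
            row[code] = int(bool(r.presence[code]))
        rows.append(row)
    columns = list(_BASE_COLUMNS) + list(catalog.codes)
    return pd.DataFrame(rows, columns=columns)


def frame_to_records(
    frame: pd.DataFrame, catalog: Optional[FoodGroupCatalog] = None
) -> list[RetailerRecord]:
    catalog = catalog or default_catalog()
    missing = [c for c in _BASE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"retailer table missing column(s) {missing}")
    return [
        _row_to_record(row, catalog)
        for row in frame.to_dict(orient="records")
    ]


def write_retailers(
    records: Sequence[RetailerRecord],
    path: str | Path,
    catalog: Optional[FoodGroupCatalog] = None,
) -> None:
    """Write records as CSV or (by extension) GeoJSON points."""
    catalog = catalog or default_catalog()
    path = Path(path)
    frame = records_to_frame(records, catalog)
    if path.suffix.lower() in (".geojson", ".json"):
        feats = []
        for row in frame.to_dict(orient="records"):
            lon, lat = row.pop("lon"), row.pop("lat")
            feats.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [lon, lat]},
                    "properties": row,
                }
            )
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)
    else:
        frame.to_csv(path, index=False)


def read_window(path: str | Path, crs_note: str = "as supplied") -> StudyWindow:
    """Read a study window from a GeoJSON Polygon/MultiPolygon file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"study window file not found: {path}")
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        geoms = [shapely_shape(f["geometry"]) for f in gj["features"]]
        geom = shapely.union_all(geoms) if len(geoms) > 1 else geoms[0]
    elif gj.get("type") == "Feature":
        geom = shapely_shape(gj["geometry"])
    else:
        geom = shapely_shape(gj)
    return StudyWindow(polygon=geom, crs_note=crs_note)


def write_window(window: StudyWindow, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(shapely_mapping(window.polygon), fh)


def write_scored_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Serialize a scored table to CSV (round-trips with read_scored_table)."""
    frame.to_csv(path, index=False, float_format="%.12g")


def read_scored_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
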