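"""Catalog structure, retailer I/O, and the planar projection."""

import math

import numpy as np
import pandas as pd
import pytest

from rfeq.catalog import (
    CatalogError,
    default_catalog,
    load_catalog,
    write_catalog,
)
from rfeq.io import (
    TYPOLOGIES,
    ValidationError,
    frame_to_records,
    read_retailers,
    read_scored_table,
    write_retailers,
    write_scored_table,
)
from rfeq.projection import lonlat_to_enu, plane_to_lonlat, project_to_plane
from tests.conftest import make_record

# WGS84 constants, used only to build independent geodesic oracles here
_A, _F = 6378137.0, 1 / 298.257223563
_E2 = _F * (2 - _F)


def _meridian_radius(lat_deg):
    s = math.sin(math.radians(lat_deg))
    return _A * (1 - _E2) / (1 - _E2 * s * s) ** 1.5


def _normal_radius(lat_deg):
    s = math.sin(math.radians(lat_deg))
    return _A / math.sqrt(1 - _E2 * s * s)


class TestCatalog:
    def test_builtin_structure(self):
        cat = load_catalog(None)
        assert len(cat.healthy) == 9
        assert len(cat.unhealthy) == 8
        assert cat["processed_meat"].weight == 2
        assert all(g.weight == 1 for g in cat if g.code != "processed_meat")
        assert sum(g.weight for g in cat.healthy) == 9
        assert sum(g.weight for g in cat.unhealthy) == 9

    def test_config_roundtrip_equals_builtin(self, tmp_path):
        p = tmp_path / "catalog.csv"
        write_catalog(default_catalog(), p)
        assert load_catalog(p) == default_catalog()

    def test_downweighted_processed_meat_rejected(self, tmp_path):
        """Weight 1 for processed meats breaks the unhealthy sum (8 != 9)."""
        import csv

        p = tmp_path / "catalog.csv"
        with open(p, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["code", "label", "polarity", "weight"])
            for g in default_catalog():
                w = 1 if g.code == "processed_meat" else g.weight
                writer.writerow([g.code, g.label, g.polarity, w])
        with pytest.raises(CatalogError, match="sum"):
            load_catalog(p)

    def test_malformed_config_names_field(self, tmp_path):
        p = tmp_path / "catalog.csv"
        p.write_text("code,label,weight\nx,y,1\n")
        with pytest.raises(CatalogError, match="polarity"):
            load_catalog(p)


class TestRetailerIO:
    def _records(self, catalog, n=3):
        return [
            make_record(
                catalog,
                rid=f"r{i}",
                lon=36.88 + i * 1e-3,
                lat=-1.31,
                present=("dglv", "ssb") if i % 2 else ("legumes",),
            )
            for i in range(n)
        ]

    def test_csv_count_and_order_preserved(self, catalog, tmp_path):
        recs = self._records(catalog)
        p = tmp_path / "r.csv"
        write_retailers(recs, p, catalog)
        back = read_retailers(p, catalog)
        assert len(back) == 3
        assert [r.id for r in back] == [r.id for r in recs]
        assert back == recs

    def test_geojson_csv_equivalence(self, catalog, tmp_path):
        recs = self._records(catalog)
        pc, pg = tmp_path / "r.csv", tmp_path / "r.geojson"
        write_retailers(recs, pc, catalog)
        write_retailers(recs, pg, catalog)
        assert read_retailers(pc, catalog) == read_retailers(pg, catalog)

    def test_unknown_typology_lists_allowed_levels(self, catalog, tmp_path):
        recs = self._records(catalog)
        frame = pd.read_csv(write_retailers(recs, tmp_path / "r.csv", catalog)
                            or tmp_path / "r.csv")
        frame.loc[0, "typology"] = "petrol station"
        frame.to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(ValidationError) as exc:
            read_retailers(tmp_path / "bad.csv", catalog)
        for typ in TYPOLOGIES:
            assert typ in str(exc.value)

    def test_missing_presence_column_names_group(self, catalog, tmp_path):
        recs = self._records(catalog)
        frame = pd.read_csv(write_retailers(recs, tmp_path / "r.csv", catalog)
                            or tmp_path / "r.csv")
        frame = frame.drop(columns=["legumes"])
        with pytest.raises(ValidationError, match="legumes"):
            frame_to_records(frame, catalog)

    def test_scored_table_roundtrip(self, catalog, tmp_path):
        from rfeq.indices import score_table

        scored = score_table(self._records(catalog), catalog)
        p = tmp_path / "scored.csv"
        write_scored_table(scored, p)
        back = read_scored_table(p)
        pd.testing.assert_frame_equal(back, scored, check_dtype=False)


class TestProjection:
    def test_meridian_step_matches_geodesic(self):
        """0.001 deg of latitude at mid-latitude spans ~111.2 m."""
        pts = project_to_plane(np.array([[10.0, 45.0], [10.0, 45.001]]))
        d = np.hypot(*(pts[1] - pts[0]))
        assert d == pytest.approx(111.2, abs=0.2)
        # and agrees with the meridian-arc oracle to 0.1%
        oracle = _meridian_radius(45.0005) * math.radians(0.001)
        assert d == pytest.approx(oracle, rel=1e-3)

    def test_identical_points_zero_distance(self):
        pts = project_to_plane(np.array([[36.88, -1.31], [36.88, -1.31]]))
        assert np.hypot(*(pts[1] - pts[0])) == 0.0

    def test_345_triangle_preserved(self):
        """Geodesic 3-4-5 right triangle at ~100 m scale keeps its ratios."""
        lat0, lon0 = -1.31, 36.88
        north = 300.0 / _meridian_radius(lat0)
        east = 400.0 / (_normal_radius(lat0) * math.cos(math.radians(lat0)))
        lonlat = np.array(
            [
                [lon0, lat0],
                [lon0, lat0 + math.degrees(north)],
                [lon0 + math.degrees(east), lat0],
            ]
        )
        pts = project_to_plane(lonlat)
        a = np.hypot(*(pts[1] - pts[0]))
        b = np.hypot(*(pts[2] - pts[0]))
        c = np.hypot(*(pts[2] - pts[1]))
        assert a == pytest.approx(300.0, rel=1e-3)
        assert b == pytest.approx(400.0, rel=1e-3)
        assert c == pytest.approx(500.0, rel=1e-3)

    def test_wide_extent_rejected(self):
        with pytest.raises(ValueError, match="projection"):
            project_to_plane(np.array([[0.0, 0.0], [4.0, 0.0]]))

    def test_plane_roundtrip(self, rng):
        origin = (36.9, -1.3)
        xy = rng.uniform(-5000, 5000, (20, 2))
        back = lonlat_to_enu(plane_to_lonlat(xy, origin), origin)
        assert np.allclose(back, xy, atol=1e-6)
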