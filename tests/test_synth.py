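"""Synthetic environment generator: determinism, mixtures, clustering."""

import numpy as np
import pytest

from rfeq.indices import score_table
from rfeq.io import records_to_frame
from rfeq.projection import project_to_plane
from rfeq.synth import (
    DEFAULT_STOCKING,
    EnvironmentConfig,
    generate_environment,
    preset,
)


class TestPresets:
    def test_ward_areas(self):
        assert preset("urban").window.area == pytest.approx(5.0e6, rel=1e-6)
        assert preset("rural").window.area == pytest.approx(446.2e6, rel=1e-6)

    def test_presets_validate(self):
        for name in ("rural", "urban"):
            cfg = preset(name)
            assert isinstance(cfg, EnvironmentConfig)

    def test_rural_has_broader_clustering_scale(self):
        assert preset("rural").sigma > preset("urban").sigma

    def test_unknown_preset(self):
        with pytest.raises(ValueError):
            preset("suburban")

    def test_designed_stall_mobile_ratio(self):
        assert preset("urban").designed_rate_ratio(
            "stall_tabletop", "mobile", "hrfes"
        ) == pytest.approx(3.0)


class TestGeneration:
    def test_determinism(self):
        cfg = preset("urban", n_outlets=200, seed=99)
        r1, t1 = generate_environment(cfg)
        r2, t2 = generate_environment(cfg)
        assert r1 == r2
        assert t1.n_parents == t2.n_parents

    def test_typology_proportions_at_survey_scale(self):
        """Combined wards at n=2086: stall share ~26.5%, female ~71%."""
        ru, _ = generate_environment(preset("rural", n_outlets=894, seed=4))
        ur, _ = generate_environment(preset("urban", n_outlets=1192, seed=5))
        frame = records_to_frame(list(ru) + list(ur))
        n = len(frame)
        assert n == 2086
        p_stall = (frame.typology == "stall_tabletop").mean()
        expect = (0.283 * 894 + 0.251 * 1192) / 2086
        se = np.sqrt(expect * (1 - expect) / n)
        assert abs(p_stall - expect) <= 2 * se + 1e-9
        p_f = (frame.gender == "female").mean()
        expect_f = (0.707 * 894 + 0.718 * 1192) / 2086
        se_f = np.sqrt(expect_f * (1 - expect_f) / n)
        assert abs(p_f - expect_f) <= 2 * se_f + 1e-9

    def test_points_inside_window(self):
        cfg = preset("urban", n_outlets=300, seed=1)
        recs, _ = generate_environment(cfg)
        pts = project_to_plane(recs, origin=cfg.anchor_lonlat)
        minx, miny, maxx, maxy = cfg.window.polygon.bounds
        pad = 0.5  # projection round-trip tolerance, meters
        assert (pts[:, 0] >= minx - pad).all() and (pts[:, 0] <= maxx + pad).all()
        assert (pts[:, 1] >= miny - pad).all() and (pts[:, 1] <= maxy + pad).all()

    def test_farmgate_stocks_nothing_unhealthy(self, catalog):
        cfg = preset("rural", n_outlets=800, seed=2)
        recs, _ = generate_environment(cfg)
        scored = score_table(recs)
        fg = scored[scored.typology == "farmgate"]
        if len(fg):
            assert (fg["urfes"] == 0).all()

    def test_rural_urban_index_contrast(self):
        """Rural outlets score higher on both sides at the retailer level."""
        ru, _ = generate_environment(preset("rural", n_outlets=894, seed=6))
        ur, _ = generate_environment(preset("urban", n_outlets=1192, seed=7))
        s_ru, s_ur = score_table(ru), score_table(ur)
        assert s_ru["hrfes"].mean() > s_ur["hrfes"].mean()
        assert s_ru["urfes"].mean() > s_ur["urfes"].mean()
        # and the levels sit in the observed low single digits
        assert 1.0 < s_ru["hrfes"].mean() < 3.0
        assert 1.0 < s_ur["hrfes"].mean() < 3.0

    def test_typology_by_cluster_mode(self):
        from dataclasses import replace

        cfg = replace(preset("urban", n_outlets=300, seed=3),
                      typology_by_cluster=True)
        recs, truth = generate_environment(cfg)
        assert len(recs) == 300
        assert truth.n_parents >= 1


class TestConfigValidation:
    def test_bad_mixture_sum(self):
        cfg = preset("urban")
        mix = dict(cfg.typology_mix)
        mix["kiosk"] += 0.5
        with pytest.raises(ValueError, match="sums"):
            EnvironmentConfig(
                window=cfg.window, anchor_lonlat=cfg.anchor_lonlat,
                n_outlets=10, stratum="urban", sigma=50.0, mean_offspring=5.0,
                typology_mix=mix,
            )

    def test_bad_sigma(self):
        cfg = preset("urban")
        with pytest.raises(ValueError, match="sigma"):
            EnvironmentConfig(
                window=cfg.window, anchor_lonlat=cfg.anchor_lonlat,
                n_outlets=10, stratum="urban", sigma=-1.0, mean_offspring=5.0,
            )

    def test_stocking_out_of_range(self):
        cfg = preset("urban")
        bad = dict(DEFAULT_STOCKING)
        h, u = bad["kiosk"]
        bad["kiosk"] = (tuple(p * 20 for p in h), u)
        with pytest.raises(ValueError, match="outside"):
            EnvironmentConfig(
                window=cfg.window, anchor_lonlat=cfg.anchor_lonlat,
                n_outlets=10, stratum="urban", sigma=50.0, mean_offspring=5.0,
                stocking=bad,
            )
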