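"""Buffer pooling: closed-ball neighborhoods, union re-scoring, monotonicity."""

import numpy as np
import pytest

from rfeq.catalog import default_catalog
from rfeq.neighborhood import (
    BufferSpec,
    buffer_presence,
    neighbors_within,
    score_buffers,
)
from tests.conftest import make_record

CAT = default_catalog()


class TestNeighborsWithin:
    def test_isolated_point_is_own_neighbor(self):
        pts = np.array([[0.0, 0.0], [1000.0, 0.0]])
        assert neighbors_within(pts, 0, 50.0) == {0}

    def test_sixty_meter_pair(self):
        pts = np.array([[0.0, 0.0], [60.0, 0.0]])
        assert neighbors_within(pts, 0, 50.0) == {0}
        assert neighbors_within(pts, 1, 50.0) == {1}
        assert neighbors_within(pts, 0, 100.0) == {0, 1}
        assert neighbors_within(pts, 1, 100.0) == {0, 1}

    def test_closed_ball_boundary(self):
        pts = np.array([[0.0, 0.0], [100.0, 0.0]])
        assert neighbors_within(pts, 0, 100.0) == {0, 1}

    def test_symmetry(self, rng):
        pts = rng.uniform(0, 500, (30, 2))
        for r in (50.0, 120.0):
            for i in range(30):
                for j in neighbors_within(pts, i, r):
                    assert i in neighbors_within(pts, j, r)

    def test_focal_out_of_range(self):
        with pytest.raises(IndexError):
            neighbors_within(np.zeros((3, 2)), 5, 10.0)


class TestBufferPresence:
    def test_disjoint_union(self, catalog):
        recs = [
            make_record(catalog, rid="a", present=("dglv",)),
            make_record(catalog, rid="b", present=("legumes",)),
        ]
        pooled = buffer_presence(recs, {0, 1}, catalog)
        assert pooled["dglv"] and pooled["legumes"]
        assert sum(pooled[c] for c in catalog.healthy_codes) == 2

    def test_singleton_identity(self, catalog):
        recs = [make_record(catalog, rid="a", present=("ssb", "citrus"))]
        assert buffer_presence(recs, {0}, catalog) == dict(recs[0].presence)

    def test_all_absent_is_identity_element(self, catalog):
        recs = [
            make_record(catalog, rid="a", present=("ssb", "citrus")),
            make_record(catalog, rid="none", present=()),
        ]
        assert buffer_presence(recs, {0, 1}, catalog) == dict(recs[0].presence)

    def test_empty_set_rejected(self, catalog):
        with pytest.raises(ValueError):
            buffer_presence([], set(), catalog)


class TestBufferSpec:
    def test_defaults(self):
        assert BufferSpec().radii == (50.0, 100.0, 200.0)

    @pytest.mark.parametrize("radii", [(), (-5.0,), (100.0, 50.0)])
    def test_invalid_radii(self, radii):
        with pytest.raises(ValueError):
            BufferSpec(radii=radii)


def _toy_layout(catalog):
    """Five outlets on a line with known pairwise distances (meters)."""
    xs = [0.0, 40.0, 90.0, 260.0, 1000.0]
    groups = [
        ("dglv",),
        ("legumes", "ssb"),
        ("whole_grain",),
        ("processed_meat", "citrus"),
        ("deep_fried",),
    ]
    recs = [
        make_record(catalog, rid=f"t{i}", present=g)
        for i, g in enumerate(groups)
    ]
    pts = np.array([[x, 0.0] for x in xs])
    return recs, pts


class TestScoreBuffers:
    def test_toy_layout_matches_brute_force(self, catalog):
        """Hand-poolable 5-outlet line agrees with the vectorized path."""
        recs, pts = _toy_layout(catalog)
        spec = BufferSpec(radii=(50.0, 200.0))
        out = score_buffers(recs, spec, catalog, points=pts)
        for i in range(len(recs)):
            for r, tag in ((50.0, "r50"), (200.0, "r200")):
                nb = neighbors_within(pts, i, r)
                pooled = buffer_presence(recs, nb, catalog)
                h = sum(1 for c in CAT.healthy_codes if pooled[c])
                u = sum(CAT[c].weight for c in CAT.unhealthy_codes if pooled[c])
                assert out.loc[i, f"hrfes_{tag}"] == h
                assert out.loc[i, f"urfes_{tag}"] == u
                assert out.loc[i, f"rfeqi_{tag}"] == h - u + 9

    def test_toy_layout_expected_values(self, catalog):
        # hand computation: at r=50 outlet 1 pools outlets 0,1,2
        recs, pts = _toy_layout(catalog)
        out = score_buffers(recs, BufferSpec(radii=(50.0,)), catalog, points=pts)
        assert out.loc[1, "hrfes_r50"] == 3  # dglv + legumes + whole_grain
        assert out.loc[1, "urfes_r50"] == 1  # ssb only
        assert out.loc[4, "hrfes_r50"] == 0  # isolated outlet
        assert out.loc[4, "urfes_r50"] == 1

    def test_coincident_outlets_pool_everything(self, catalog):
        recs = [
            make_record(catalog, rid="a", present=("dglv",)),
            make_record(catalog, rid="b", present=("ssb",)),
            make_record(catalog, rid="c", present=("processed_meat",)),
        ]
        pts = np.zeros((3, 2))
        out = score_buffers(recs, BufferSpec(radii=(50.0,)), catalog, points=pts)
        assert (out["hrfes_r50"] == 1).all()
        assert (out["urfes_r50"] == 3).all()

    def test_radius_monotonicity_and_domination(self, catalog, rng):
        """Buffer scores are non-decreasing in radius and dominate the
        retailer-level score (set union dominates its elements)."""
        recs = []
        for i in range(60):
            present = tuple(c for c in catalog.codes if rng.random() < 0.3)
            recs.append(make_record(catalog, rid=f"r{i}", present=present))
        pts = rng.uniform(0, 400, (60, 2))
        out = score_buffers(
            recs, BufferSpec(radii=(50.0, 100.0, 200.0)), catalog, points=pts
        )
        for side in ("hrfes", "urfes"):
            assert (out[f"{side}_r50"] >= out[side]).all()
            assert (out[f"{side}_r100"] >= out[f"{side}_r50"]).all()
            assert (out[f"{side}_r200"] >= out[f"{side}_r100"]).all()

    def test_pooling_order_independent(self, catalog, rng):
        recs = []
        for i in range(20):
            present = tuple(c for c in catalog.codes if rng.random() < 0.3)
            recs.append(make_record(catalog, rid=f"r{i}", present=present))
        pts = rng.uniform(0, 150, (20, 2))
        out = score_buffers(recs, BufferSpec(radii=(80.0,)), catalog, points=pts)
        perm = rng.permutation(20)
        out_p = score_buffers(
            [recs[i] for i in perm],
            BufferSpec(radii=(80.0,)),
            catalog,
            points=pts[perm],
        )
        for k, i in enumerate(perm):
            assert out_p.loc[k, "hrfes_r80"] == out.loc[i, "hrfes_r80"]
            assert out_p.loc[k, "urfes_r80"] == out.loc[i, "urfes_r80"]
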