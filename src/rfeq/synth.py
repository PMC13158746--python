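"""Synthetic retail food environments.

Generates outlet tables with the statistical structure the analysis
assumes, so every pipeline stage is testable without survey data:

* locations follow a Thomas cluster process (uniform parents, isotropic
  Gaussian offspring with scale ``sigma``) clipped to a polygon window —
  the simplest parametric process producing local clustering with one
  dominant spatial scale;
* typology, gender and shelf-space categories are drawn from closed
  mixtures (preset mixtures follow the surveyed rural and urban wards);
* each food group's presence is Bernoulli with a probability conditional
  on the outlet's typology (the stocking matrix).

Because the survey does not publish typology-conditional stocking
probabilities, the default stocking matrix encodes the qualitative ordering
of the fitted rate ratios: stalls/tabletops are healthy-heavy (with mobile
retailers at exactly one third of the stall probabilities, a designed
stall-vs-mobile healthy-score rate ratio of 3), supermarkets, kiosks,
restaurants and home vendors unhealthy-heavy, butchers dominated by red
meat, and farmgate sellers stocking no unhealthy group at all (which
exercises the regression's separation path).

Two presets bundle realistic study conditions: ``rural`` (~446.2 km^2 ward,
n = 894, broad clustering) and ``urban`` (~5.0 km^2 ward, n = 1192, tight
clustering), so the rural pattern exhibits a larger K-deviation scale.

All randomness flows from a single seeded generator; the emitted table is
exactly reproducible from config + seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from shapely.geometry import box

from .catalog import FoodGroupCatalog, default_catalog
from .io import (
    GENDERS,
    RetailerRecord,
    SHELF_SPACE_LEVELS,
    STRATA,
    StudyWindow,
    TYPOLOGIES,
)
from .projection import plane_to_lonlat

__all__ = [
    "EnvironmentConfig",
    "SyntheticTruth",
    "generate_environment",
    "preset",
    "DEFAULT_STOCKING",
]

_H_CODES = (
    "dglv", "vita_veg", "other_veg", "vita_fruit", "citrus",
    "other_fruit", "legumes", "nuts_seeds", "whole_grain",
)
_U_CODES = (
    "ssb", "baked_sweets", "other_sweets", "processed_meat",
    "red_meat", "deep_fried", "fast_food", "salty_snacks",
)

_STALL_HEALTHY = (0.70, 0.18, 0.78, 0.12, 0.27, 0.48, 0.33, 0.18, 0.26)

# typology -> (9 healthy probs, 8 unhealthy probs)
DEFAULT_STOCKING: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    "stall_tabletop": (
        _STALL_HEALTHY,
        (0.05, 0.04, 0.08, 0.01, 0.02, 0.08, 0.03, 0.08),
    ),
    "mobile": (
        tuple(p / 3.0 for p in _STALL_HEALTHY),
        (0.15, 0.06, 0.10, 0.01, 0.01, 0.12, 0.06, 0.12),
    ),
    "kiosk": (
        (0.06, 0.02, 0.10, 0.02, 0.05, 0.09, 0.14, 0.08, 0.34),
        (0.72, 0.50, 0.62, 0.06, 0.02, 0.25, 0.22, 0.66),
    ),
    "cooked_food_street": (
        (0.30, 0.08, 0.35, 0.05, 0.10, 0.18, 0.25, 0.08, 0.30),
        (0.25, 0.30, 0.25, 0.03, 0.08, 0.72, 0.40, 0.20),
    ),
    "butcher": (
        (0.02, 0.01, 0.05, 0.01, 0.01, 0.02, 0.02, 0.01, 0.03),
        (0.05, 0.02, 0.03, 0.20, 0.95, 0.15, 0.05, 0.03),
    ),
    "cereal_shop": (
        (0.05, 0.02, 0.06, 0.02, 0.03, 0.05, 0.80, 0.40, 0.89),
        (0.10, 0.18, 0.15, 0.01, 0.01, 0.05, 0.08, 0.30),
    ),
    "wholesaler": (
        (0.08, 0.02, 0.08, 0.02, 0.04, 0.06, 0.45, 0.20, 0.60),
        (0.50, 0.30, 0.40, 0.05, 0.02, 0.08, 0.15, 0.50),
    ),
    "modern_restaurant": (
        (0.40, 0.10, 0.45, 0.08, 0.15, 0.25, 0.30, 0.10, 0.45),
        (0.85, 0.45, 0.40, 0.15, 0.35, 0.85, 0.75, 0.30),
    ),
    "home_based": (
        (0.30, 0.08, 0.30, 0.06, 0.10, 0.20, 0.25, 0.10, 0.35),
        (0.60, 0.50, 0.55, 0.05, 0.03, 0.45, 0.30, 0.50),
    ),
    "mom_and_pop": (
        (0.25, 0.06, 0.28, 0.05, 0.10, 0.18, 0.40, 0.20, 0.75),
        (0.70, 0.55, 0.60, 0.10, 0.03, 0.20, 0.25, 0.70),
    ),
    "supermarket": (
        (0.25, 0.10, 0.28, 0.08, 0.15, 0.25, 0.45, 0.30, 0.70),
        (0.95, 0.90, 0.92, 0.55, 0.25, 0.15, 0.30, 0.95),
    ),
    "farmgate": (
        (0.55, 0.15, 0.60, 0.12, 0.20, 0.45, 0.30, 0.10, 0.15),
        (0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
    ),
}

# surveyed typology shares by ward (percent / 100)
URBAN_TYPOLOGY_MIX = {
    "cooked_food_street": 0.317, "kiosk": 0.268, "stall_tabletop": 0.251,
    "mobile": 0.097, "butcher": 0.033, "cereal_shop": 0.012,
    "wholesaler": 0.012, "modern_restaurant": 0.003, "home_based": 0.003,
    "mom_and_pop": 0.002, "farmgate": 0.001, "supermarket": 0.001,
}
RURAL_TYPOLOGY_MIX = {
    "cooked_food_street": 0.169, "kiosk": 0.388, "stall_tabletop": 0.283,
    "mobile": 0.025, "butcher": 0.047, "cereal_shop": 0.025,
    "wholesaler": 0.018, "modern_restaurant": 0.017, "home_based": 0.009,
    "mom_and_pop": 0.002, "farmgate": 0.013, "supermarket": 0.004,
}
URBAN_GENDER_MIX = {
    "female": 0.718, "male": 0.240, "mixed": 0.025,
    "multiple_females": 0.013, "multiple_males": 0.004,
}
RURAL_GENDER_MIX = {
    "female": 0.707, "male": 0.272, "mixed": 0.016,
    "multiple_females": 0.002, "multiple_males": 0.003,
}
URBAN_SHELF_MIX = {
    "food_100": 0.582, "food_75_99": 0.268, "food_50_74": 0.089,
    "food_25_49": 0.042, "below_25": 0.019,
}
RURAL_SHELF_MIX = {
    "food_100": 0.557, "food_75_99": 0.274, "food_50_74": 0.137,
    "food_25_49": 0.024, "below_25": 0.008,
}


def _check_mixture(name: str, mix: dict, levels: tuple[str, ...]) -> None:
    extra = set(mix) - set(levels)
    if extra:
        raise ValueError(f"{name}: unknown level(s) {sorted(extra)}")
    total = sum(mix.values())
    if not math.isclose(total, 1.0, abs_tol=1e-6):
        raise ValueError(f"{name}: mixture sums to {total}, expected 1")
    if any(p < 0 for p in mix.values()):
        raise ValueError(f"{name}: negative probability")


@dataclass(frozen=True)
class EnvironmentConfig:
    """Study conditions for one synthetic ward."""

    window: StudyWindow
    anchor_lonlat: tuple[float, float]
    n_outlets: int
    stratum: str
    sigma: float  # offspring dispersion, meters
    mean_offspring: float
    parent_intensity: Optional[float] = None  # parents per m^2; derived if None
    typology_mix: dict = field(default_factory=lambda: dict(URBAN_TYPOLOGY_MIX))
    gender_mix: dict = field(default_factory=lambda: dict(URBAN_GENDER_MIX))
    shelf_mix: dict = field(default_factory=lambda: dict(URBAN_SHELF_MIX))
    stocking: dict = field(default_factory=lambda: dict(DEFAULT_STOCKING))
    healthy_scale: float = 1.0  # stratum-level multiplier on healthy stocking
    typology_by_cluster: bool = False
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_outlets < 1:
            raise ValueError("n_outlets must be >= 1")
        if self.stratum not in STRATA:
            raise ValueError(f"stratum must be one of {STRATA}")
        if self.sigma <= 0:
            raise ValueError("offspring dispersion sigma must be > 0")
        if self.mean_offspring <= 0:
            raise ValueError("mean offspring per parent must be > 0")
        if self.healthy_scale <= 0:
            raise ValueError("healthy_scale must be > 0")
        _check_mixture("typology_mix", self.typology_mix, TYPOLOGIES)
        _check_mixture("gender_mix", self.gender_mix, GENDERS)
        _check_mixture("shelf_mix", self.shelf_mix, SHELF_SPACE_LEVELS)
        for typ in TYPOLOGIES:
            if typ not in self.stocking:
                raise ValueError(f"stocking matrix missing typology {typ!r}")
            h, u = self.stocking[typ]
            if len(h) != len(_H_CODES) or len(u) != len(_U_CODES):
                raise ValueError(f"stocking[{typ!r}] has wrong group count")
            if any(not (0.0 <= p <= 1.0) for p in list(h) + list(u)):
                raise ValueError(
                    f"stocking[{typ!r}] probabilities outside [0, 1]"
                )
            if any(p * self.healthy_scale > 1.0 + 1e-12 for p in h):
                raise ValueError(
                    f"healthy_scale {self.healthy_scale} pushes a "
                    f"stocking[{typ!r}] probability above 1"
                )
        # the window must plausibly hold the requested outlets
        if self.window.area < self.n_outlets * 1.0:  # > 1 outlet per m^2
            raise ValueError(
                f"infeasible: {self.n_outlets} outlets in "
                f"{self.window.area:.1f} m^2 window"
            )

    def expected_index_mean(self, typology: str, side: str = "hrfes") -> float:
        """Expected score for one typology under the stocking matrix."""
        h, u = self.stocking[typology]
        if side == "hrfes":
            return float(sum(p * self.healthy_scale for p in h))
        weights = [2 if c == "processed_meat" else 1 for c in _U_CODES]
        return float(sum(w * p for w, p in zip(weights, u)))

    def designed_rate_ratio(
        self, typology: str, reference: str = "mobile", side: str = "hrfes"
    ) -> float:
        """Designed expected-score ratio between two typologies."""
        return self.expected_index_mean(typology, side) / self.expected_index_mean(
            reference, side
        )


@dataclass(frozen=True)
class SyntheticTruth:
    """Generating parameters bundled with the emitted table."""

    config: EnvironmentConfig
    seed: Optional[int]
    n_parents: int
    parent_xy: np.ndarray
    designed_hrfes_ratio_stall_vs_mobile: float


def _thomas_points(
    config: EnvironmentConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Thomas-process points clipped to the window, exactly n_outlets of
    them; returns (points, parent index per point)."""
    import shapely

    win = config.window.polygon
    minx, miny, maxx, maxy = win.bounds
    pad = 3.0 * config.sigma
    ext_area = (maxx - minx + 2 * pad) * (maxy - miny + 2 * pad)
    kappa = config.parent_intensity
    if kappa is None:
        kappa = config.n_outlets / (config.mean_offspring * config.window.area)
    # inflate so that the expected in-window yield comfortably exceeds n
    boost = 1.3
    for _ in range(25):
        n_par = rng.poisson(kappa * boost * ext_area)
        if n_par == 0:
            boost *= 1.6
            continue
        parents = np.column_stack(
            [
                rng.uniform(minx - pad, maxx + pad, n_par),
                rng.uniform(miny - pad, maxy + pad, n_par),
            ]
        )
        counts = rng.poisson(config.mean_offspring, n_par)
        parent_ids = np.repeat(np.arange(n_par), counts)
        offs = parents[parent_ids] + rng.normal(
            0.0, config.sigma, (counts.sum(), 2)
        )
        keep = shapely.contains_xy(win, offs[:, 0], offs[:, 1])
        offs, parent_ids = offs[keep], parent_ids[keep]
        if len(offs) >= config.n_outlets:
            sel = rng.choice(len(offs), size=config.n_outlets, replace=False)
            sel.sort()
            return offs[sel], parent_ids[sel]
        boost *= 1.6
    raise ValueError(
        "infeasible cluster configuration: could not place the requested "
        "number of outlets inside the window"
    )


def generate_environment(
    config: EnvironmentConfig, catalog: Optional[FoodGroupCatalog] = None
) -> tuple[list[RetailerRecord], SyntheticTruth]:
    """Generate one synthetic retail environment from its config."""
    catalog = catalog or default_catalog()
    rng = np.random.default_rng(config.seed)
    points, parent_ids = _thomas_points(config, rng)
    n = config.n_outlets

    typ_levels = list(config.typology_mix)
    typ_p = np.array([config.typology_mix[t] for t in typ_levels])
    typ_p = typ_p / typ_p.sum()
    if config.typology_by_cluster:
        uniq = np.unique(parent_ids)
        cluster_typ = {
            pid: typ_levels[i]
            for pid, i in zip(uniq, rng.choice(len(typ_levels), len(uniq), p=typ_p))
        }
        typology = np.array([cluster_typ[p] for p in parent_ids], dtype=object)
    else:
        typology = np.array(typ_levels, dtype=object)[
            rng.choice(len(typ_levels), n, p=typ_p)
        ]

    g_levels = list(config.gender_mix)
    g_p = np.array([config.gender_mix[g] for g in g_levels])
    gender = np.array(g_levels, dtype=object)[
        rng.choice(len(g_levels), n, p=g_p / g_p.sum())
    ]
    s_levels = list(config.shelf_mix)
    s_p = np.array([config.shelf_mix[s] for s in s_levels])
    shelf = np.array(s_levels, dtype=object)[
        rng.choice(len(s_levels), n, p=s_p / s_p.sum())
    ]

    probs = np.empty((n, len(_H_CODES) + len(_U_CODES)))
    for typ in set(typology.tolist()):
        h, u = config.stocking[typ]
        row = np.array([p * config.healthy_scale for p in h] + list(u))
        probs[typology == typ] = row
    presence = rng.random(probs.shape) < probs

    lonlat = plane_to_lonlat(points, config.anchor_lonlat)
    codes = list(_H_CODES) + list(_U_CODES)
    records = []
    for i in range(n):
        records.append(
            RetailerRecord(
                id=f"{config.stratum}-{i:05d}",
                lon=float(lonlat[i, 0]),
                lat=float(lonlat[i, 1]),
                stratum=config.stratum,
                typology=str(typology[i]),
                gender=str(gender[i]),
                shelf_space=str(shelf[i]),
                presence={c: bool(presence[i, j]) for j, c in enumerate(codes)},
            ).validate(catalog)
        )
    truth = SyntheticTruth(
        config=config,
        seed=config.seed,
        n_parents=int(len(np.unique(parent_ids))),
        parent_xy=points,
        designed_hrfes_ratio_stall_vs_mobile=config.designed_rate_ratio(
            "stall_tabletop", "mobile", "hrfes"
        ),
    )
    return records, truth


def _square_window(area_m2: float) -> StudyWindow:
    side = math.sqrt(area_m2)
    return StudyWindow(
        polygon=box(-side / 2, -side / 2, side / 2, side / 2),
        crs_note="local ENU meters about the ward anchor",
    )


def preset(name: str, n_outlets: Optional[int] = None, seed: Optional[int] = None) -> EnvironmentConfig:
    """Named study conditions: ``rural`` (~446.2 km^2, n=894, broad
    clustering) or ``urban`` (~5.0 km^2, n=1192, tight clustering)."""
    if name == "rural":
        return EnvironmentConfig(
            window=_square_window(446.2e6),
            anchor_lonlat=(37.35, -1.85),
            n_outlets=n_outlets or 894,
            stratum="rural",
            sigma=170.0,
            mean_offspring=10.0,
            typology_mix=dict(RURAL_TYPOLOGY_MIX),
            gender_mix=dict(RURAL_GENDER_MIX),
            shelf_mix=dict(RURAL_SHELF_MIX),
            healthy_scale=1.12,
            seed=seed,
        )
    if name == "urban":
        return EnvironmentConfig(
            window=_square_window(5.0e6),
            anchor_lonlat=(36.88, -1.31),
            n_outlets=n_outlets or 1192,
            stratum="urban",
            sigma=70.0,
            mean_offspring=8.0,
            typology_mix=dict(URBAN_TYPOLOGY_MIX),
            gender_mix=dict(URBAN_GENDER_MIX),
            shelf_mix=dict(URBAN_SHELF_MIX),
            healthy_scale=1.0,
            seed=seed,
        )
    raise ValueError(f"unknown preset {name!r}; use 'rural' or 'urban'")
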