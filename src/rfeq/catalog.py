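"""Food-group catalog backing the retail food environment quality indices.

The scoring schema is fixed: nine food groups whose availability protects
against diet-related noncommunicable disease (the healthy side, each worth
one point) and eight groups whose availability raises NCD risk (the
unhealthy side, each worth one point except processed meats, which carry a
double weight). Both sides therefore have a maximum score of nine, which is
what makes the composite quality index symmetric around its midpoint.

A catalog may also be loaded from a flat CSV config (columns ``code``,
``label``, ``polarity``, ``weight``) so that users can relabel or reorder
groups; the structural invariants (9 healthy / 8 unhealthy, weight sums of
nine on each side) are always enforced.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

__all__ = [
    "FoodGroup",
    "FoodGroupCatalog",
    "CatalogError",
    "default_catalog",
    "load_catalog",
]

HEALTHY = "healthy"
UNHEALTHY = "unhealthy"


class CatalogError(ValueError):
    """Malformed or structurally invalid food-group catalog."""


@dataclass(frozen=True)
class FoodGroup:
    """One scoring group: a machine code, a display label, a polarity and a
    positive integer weight contributed when the group is present."""

    code: str
    label: str
    polarity: str
    weight: int = 1

    def __post_init__(self) -> None:
        if self.polarity not in (HEALTHY, UNHEALTHY):
            raise CatalogError(
                f"group {self.code!r}: polarity must be "
                f"'{HEALTHY}' or '{UNHEALTHY}', got {self.polarity!r}"
            )
        if not isinstance(self.weight, int) or self.weight < 1:
            raise CatalogError(
                f"group {self.code!r}: weight must be a positive integer, "
                f"got {self.weight!r}"
            )


@dataclass(frozen=True)
class FoodGroupCatalog:
    """Ordered collection of scoring groups.

    Invariants: codes unique; exactly nine healthy and eight unhealthy
    groups; weights sum to nine on each side (the unhealthy side reaches
    nine because processed meats count double).
    """

    groups: tuple[FoodGroup, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        codes = [g.code for g in self.groups]
        if len(set(codes)) != len(codes):
            dupes = sorted({c for c in codes if codes.count(c) > 1})
            raise CatalogError(f"duplicate group codes: {dupes}")
        n_h = len(self.healthy)
        n_u = len(self.unhealthy)
        if n_h != 9 or n_u != 8:
            raise CatalogError(
                f"catalog must have exactly 9 healthy and 8 unhealthy "
                f"groups, got {n_h} healthy / {n_u} unhealthy"
            )
        s_h = sum(g.weight for g in self.healthy)
        s_u = sum(g.weight for g in self.unhealthy)
        if s_h != 9 or s_u != 9:
            raise CatalogError(
                f"group weights must sum to 9 on each side, got "
                f"healthy={s_h}, unhealthy={s_u}"
            )

    @property
    def healthy(self) -> tuple[FoodGroup, ...]:
        return tuple(g for g in self.groups if g.polarity == HEALTHY)

    @property
    def unhealthy(self) -> tuple[FoodGroup, ...]:
        return tuple(g for g in self.groups if g.polarity == UNHEALTHY)

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(g.code for g in self.groups)

    @property
    def healthy_codes(self) -> tuple[str, ...]:
        return tuple(g.code for g in self.healthy)

    @property
    def unhealthy_codes(self) -> tuple[str, ...]:
        return tuple(g.code for g in self.unhealthy)

    def __getitem__(self, code: str) -> FoodGroup:
        for g in self.groups:
            if g.code == code:
                return g
        raise KeyError(code)

    def __iter__(self):
        return iter(self.groups)

    def __len__(self) -> int:
        return len(self.groups)


# The built-in schema. Processed meats carry the double weight.
_DEFAULT_GROUPS: tuple[tuple[str, str, str, int], ...] = (
    ("dglv", "Dark-green leafy vegetables", HEALTHY, 1),
    ("vita_veg", "Vitamin A-rich, orange-colored vegetables", HEALTHY, 1),
    ("other_veg", "Other vegetables", HEALTHY, 1),
    ("vita_fruit", "Vitamin A-rich fruits", HEALTHY, 1),
    ("citrus", "Citrus fruits", HEALTHY, 1),
    ("other_fruit", "Other fruits (including red/purple/blue fruits)", HEALTHY, 1),
    ("legumes", "Legumes", HEALTHY, 1),
    ("nuts_seeds", "Nuts/seeds", HEALTHY, 1),
    ("whole_grain", "Whole grain", HEALTHY, 1),
    ("ssb", "Sodas/sugar-sweetened beverages", UNHEALTHY, 1),
    ("baked_sweets", "Baked/grain-based sweets", UNHEALTHY, 1),
    ("other_sweets", "Other sweets", UNHEALTHY, 1),
    ("processed_meat", "Processed meats", UNHEALTHY, 2),
    ("red_meat", "Unprocessed red meat", UNHEALTHY, 1),
    ("deep_fried", "Deep-fried foods", UNHEALTHY, 1),
    ("fast_food", "Food from a fast-food restaurant, or Instant noodles", UNHEALTHY, 1),
    ("salty_snacks", "Packaged salty snacks", UNHEALTHY, 1),
)


def default_catalog() -> FoodGroupCatalog:
    """The built-in 9-healthy / 8-unhealthy scoring catalog."""
    return FoodGroupCatalog(
        tuple(FoodGroup(c, l, p, w) for c, l, p, w in _DEFAULT_GROUPS)
    )


_REQUIRED_FIELDS = ("code", "label", "polarity", "weight")


def load_catalog(config_path: Optional[str | Path] = None) -> FoodGroupCatalog:
    """Load a catalog from a flat CSV config, or return the built-in one.

    The config must have a header with columns ``code``, ``label``,
    ``polarity``, ``weight`` and one row per group. Structural invariants
    are enforced after parsing; a processed-meats weight of 1, for example,
    fails because the unhealthy weights then sum to 8, not 9.
    """
    if config_path is None:
        return default_catalog()
    path = Path(config_path)
    groups: list[FoodGroup] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CatalogError(f"{path}: empty catalog config")
        missing = [f for f in _REQUIRED_FIELDS if f not in reader.fieldnames]
        if missing:
            raise CatalogError(
                f"{path}: catalog config missing field(s) {missing}; "
                f"required fields are {list(_REQUIRED_FIELDS)}"
            )
        for lineno, row in enumerate(reader, start=2):
            for f in _REQUIRED_FIELDS:
                if row.get(f) in (None, ""):
                    raise CatalogError(
                        f"{path}:{lineno}: empty value for field {f!r}"
                    )
            try:
                weight = int(row["weight"])
            except ValueError:
                raise CatalogError(
                    f"{path}:{lineno}: field 'weight' must be an integer, "
                    f"got {row['weight']!r}"
                ) from None
            groups.append(
                FoodGroup(
                    code=row["code"].strip(),
                    label=row["label"].strip(),
                    polarity=row["polarity"].strip().lower(),
                    weight=weight,
                )
            )
    return FoodGroupCatalog(tuple(groups))


def write_catalog(catalog: FoodGroupCatalog, path: str | Path) -> None:
    """Write a catalog as a flat CSV config (inverse of :func:`load_catalog`)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_REQUIRED_FIELDS)
        for g in catalog:
            writer.writerow([g.code, g.label, g.polarity, g.weight])
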