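"""Count regression of index scores on retailer characteristics.

The index scores are small non-negative counts, so associations with
retailer characteristics (typology, gender, shelf space, rural/urban
location) are modeled with a log-link count GLM and reported as incidence
rate ratios (IRRs): the exponentiated coefficient is the multiplicative
change in the expected score relative to the reference level. Poisson is
the default family (the minimal IRR-producing model); a negative binomial
option is available for overdispersed outcomes. Confidence intervals are
Wald intervals on the log scale, exponentiated.

Reference levels: mobile retailers (typology), female (gender), 100% food
space (shelf space), rural (location).

A covariate level whose outcomes are all zero separates the likelihood (the
log-rate diverges to -infinity); such terms are reported with IRR 0 and a
flagged, unbounded interval rather than a spurious finite one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import GENDERS, SHELF_SPACE_LEVELS, STRATA, TYPOLOGIES

__all__ = ["IrrTable", "fit_count_model", "REFERENCE_LEVELS"]

REFERENCE_LEVELS: dict[str, str] = {
    "typology": "mobile",
    "gender": "female",
    "shelf_space": "food_100",
    "stratum": "rural",
}

_LEVELS: dict[str, tuple[str, ...]] = {
    "typology": TYPOLOGIES,
    "gender": GENDERS,
    "shelf_space": SHELF_SPACE_LEVELS,
    "stratum": STRATA,
}

FAMILIES = ("poisson", "negative_binomial")


@dataclass(frozen=True)
class IrrTable:
    """Fitted IRR table plus model-fit summaries."""

    table: pd.DataFrame  # term, level, irr, ci_low, ci_high, p_value, separation
    outcome: str
    family: str
    n: int
    pseudo_r2: float
    aic: float

    def __post_init__(self) -> None:
        t = self.table
        ok = ~t["separation"]
        if not ((t.loc[ok, "ci_low"] <= t.loc[ok, "irr"] + 1e-12).all()
                and (t.loc[ok, "irr"] <= t.loc[ok, "ci_high"] + 1e-12).all()):
            raise ValueError("CI bounds must bracket the IRR")

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out["outcome"] = self.outcome
        out["family"] = self.family
        out.to_csv(path, index=False, float_format="%.6g")


def _design_matrix(
    scored: pd.DataFrame, covariates: Sequence[str]
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Intercept + treatment-coded dummies with fixed reference levels."""
    cols = {"const": np.ones(len(scored))}
    terms: list[tuple[str, str]] = []
    for cov in covariates:
        if cov not in _LEVELS:
            raise ValueError(
                f"unknown covariate {cov!r}; allowed: {sorted(_LEVELS)}"
            )
        ref = REFERENCE_LEVELS[cov]
        observed = set(scored[cov].unique())
        unknown = observed - set(_LEVELS[cov])
        if unknown:
            raise ValueError(
                f"covariate {cov!r} has unknown level(s) {sorted(unknown)}"
            )
        for level in _LEVELS[cov]:
            if level == ref or level not in observed:
                continue
            cols[f"{cov}[{level}]"] = (scored[cov] == level).astype(float).to_numpy()
            terms.append((cov, level))
    return pd.DataFrame(cols, index=scored.index), terms


def fit_count_model(
    scored: pd.DataFrame,
    outcome: str = "rfeqi",
    covariates: Sequence[str] = ("stratum", "shelf_space", "gender", "typology"),
    family: str = "poisson",
) -> IrrTable:
    """Fit the fixed-effects count model and return the IRR table.

    ``outcome`` may be any non-negative integer index column (retailer- or
    buffer-level). The fit is deterministic given data and family; row
    order of the input does not affect the estimates.
    """
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}, got {family!r}")
    if outcome not in scored.columns:
        raise KeyError(f"outcome column {outcome!r} not in table")
    y = scored[outcome].to_numpy(dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError(f"outcome {outcome!r} must be non-negative integers")

    X, terms = _design_matrix(scored, covariates)
    # levels whose outcomes are all zero separate the Poisson likelihood
    separated = {
        name
        for (cov, level), name in zip(terms, X.columns[1:])
        if y[X[name].to_numpy() == 1].sum() == 0
    }

    if family == "poisson":
        fam = sm.families.Poisson()
    else:
        # moment-based dispersion for the NB variance function
        mu0 = max(y.mean(), 1e-8)
        alpha = max((y.var(ddof=1) - mu0) / mu0**2, 1e-8)
        fam = sm.families.NegativeBinomial(alpha=alpha)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separation emits benign warnings
        res = sm.GLM(y, X, family=fam).fit(maxiter=200)
        null = sm.GLM(y, np.ones((len(y), 1)), family=fam).fit()

    pseudo_r2 = float(1.0 - res.llf / null.llf) if null.llf != 0 else float("nan")
    ci = res.conf_int(alpha=0.05)

    rows = []
    old = np.seterr(over="ignore")  # a wild upper bound may overflow to inf
    for (cov, level), name in zip(terms, X.columns[1:]):
        sep = name in separated
        coef = float(res.params[name])
        lo, hi = float(ci.loc[name, 0]), float(ci.loc[name, 1])
        rows.append(
            {
                "term": cov,
                "level": level,
                "irr": 0.0 if sep else float(np.exp(coef)),
                "ci_low": 0.0 if sep else float(np.exp(lo)),
                "ci_high": np.inf if sep else float(np.exp(hi)),
                "p_value": float("nan") if sep else float(res.pvalues[name]),
                "separation": sep,
            }
        )
    np.seterr(**old)
    table = pd.DataFrame(
        rows,
        columns=["term", "level", "irr", "ci_low", "ci_high", "p_value", "separation"],
    )
    return IrrTable(
        table=table,
        outcome=outcome,
        family=family,
        n=len(scored),
        pseudo_r2=pseudo_r2,
        aic=float(res.aic),
    )
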