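"""Rural/urban contrasts and categorical association tests.

Index scores are compared between strata with Welch two-sample t tests
(means) and Kruskal-Wallis rank sum tests (distributions); categorical
retailer characteristics are compared with Fisher's exact test. For tables
larger than 2x2 the exact null distribution is approximated by Monte Carlo:
tables are sampled with fixed margins (Patefield's algorithm via
scipy.stats.random_table) and the p-value is the fraction of sampled tables
at least as unlikely as the observed one under the multivariate
hypergeometric law, reported together with its simulation standard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .indices import INDEX_COLUMNS

__all__ = [
    "ContrastResult",
    "fisher_exact_rxc",
    "group_contrasts",
    "summarize_environment",
]


@dataclass(frozen=True)
class ContrastResult:
    """One test: name, statistic, p-value and per-group summaries."""

    test: str
    statistic: float
    p_value: float
    outcome: Optional[str] = None
    groups: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _log_table_prob(tables: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Multivariate hypergeometric log-probability of r x c tables with the
    given fixed margins; ``tables`` has shape (..., r, c)."""
    n = rows.sum()
    const = gammaln(rows + 1).sum() + gammaln(cols + 1).sum() - gammaln(n + 1)
    return const - gammaln(tables + 1.0).sum(axis=(-2, -1))


def fisher_exact_rxc(
    table,
    reps: int = 100_000,
    seed: Optional[int] = None,
) -> ContrastResult:
    """Fisher's exact test for an r x c contingency table.

    2x2 tables are tested exactly; larger tables use a Monte Carlo estimate
    of the exact p-value with ``reps`` sampled tables (fixed margins) and a
    recorded seed. Zero-margin rows/columns are dropped with a warning.
    """
    t = np.asarray(table)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("contingency table must be at least 2 x 2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if np.any(t < 0) or np.any(t != np.round(t)):
            raise ValueError("contingency table must hold non-negative integers")
        t = t.astype(int)

    keep_r = t.sum(axis=1) > 0
    keep_c = t.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        warnings.warn(
            "dropping zero-margin rows/columns from contingency table",
            stacklevel=2,
        )
        t = t[keep_r][:, keep_c]
        if t.shape[0] < 2 or t.shape[1] < 2:
            raise ValueError("table degenerate after dropping zero margins")

    if t.shape == (2, 2):
        _, p = stats.fisher_exact(t, alternative="two-sided")
        return ContrastResult(
            test="fisher_exact",
            statistic=float(t[0, 0]),
            p_value=float(p),
            groups={"table": t.tolist()},
        )

    if reps < 1:
        raise ValueError("reps must be >= 1 for Monte Carlo Fisher")
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    rng = np.random.default_rng(seed)
    dist = stats.random_table(rows, cols, seed=rng)
    sims = dist.rvs(size=reps)
    logp_obs = float(_log_table_prob(t[None, ...], rows, cols)[0])
    logp_sim = _log_table_prob(sims, rows, cols)
    # tables at least as unlikely as observed (tolerance guards fp ties)
    hits = int(np.sum(logp_sim <= logp_obs + 1e-9))
    p = (hits + 1) / (reps + 1)
    se = float(np.sqrt(p * (1 - p) / reps))
    return ContrastResult(
        test="fisher_exact_mc",
        statistic=logp_obs,
        p_value=float(p),
        groups={"table": t.tolist()},
        extra={"reps": reps, "seed": seed, "simulation_se": se},
    )


def _index_columns(scored: pd.DataFrame) -> list[str]:
    return [
        c
        for c in scored.columns
        if c in INDEX_COLUMNS or any(c.startswith(f"{b}_r") for b in INDEX_COLUMNS)
    ]


def group_contrasts(
    scored: pd.DataFrame,
    by: str = "stratum",
    columns: Optional[Sequence[str]] = None,
) -> list[ContrastResult]:
    """Welch t and Kruskal-Wallis contrasts of every index column by stratum.

    Requires exactly two groups for the Welch test; each group must have at
    least two observations. Group means +- SD are reported alongside.
    """
    cols = list(columns) if columns is not None else _index_columns(scored)
    if not cols:
        raise ValueError("no index columns found to contrast")
    levels = [lv for lv, g in scored.groupby(by, observed=True)]
    groups = {lv: g for lv, g in scored.groupby(by, observed=True)}
    if len(levels) != 2:
        raise ValueError(f"expected 2 groups in {by!r}, got {len(levels)}")
    for lv in levels:
        if len(groups[lv]) < 2:
            raise ValueError(f"group {lv!r} has < 2 observations")

    results: list[ContrastResult] = []
    for col in cols:
        a = groups[levels[0]][col].to_numpy(dtype=float)
        b = groups[levels[1]][col].to_numpy(dtype=float)
        summ = {
            str(lv): {
                "n": int(len(groups[lv])),
                "mean": float(groups[lv][col].mean()),
                "sd": float(groups[lv][col].std(ddof=1)),
            }
            for lv in levels
        }
        if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
            t_stat, t_p = 0.0, 1.0
        else:
            t_stat, t_p = stats.ttest_ind(a, b, equal_var=False)
        results.append(
            ContrastResult(
                test="welch_t",
                statistic=float(t_stat),
                p_value=float(t_p),
                outcome=col,
                groups=summ,
            )
        )
        try:
            with np.errstate(invalid="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                k_stat, k_p = stats.kruskal(a, b)
        except ValueError:  # all values identical
            k_stat, k_p = 0.0, 1.0
        if np.isnan(k_stat):  # complete ties also degenerate to the null
            k_stat, k_p = 0.0, 1.0
        results.append(
            ContrastResult(
                test="kruskal_wallis",
                statistic=float(k_stat),
                p_value=float(k_p),
                outcome=col,
                groups=summ,
            )
        )
    return results


def contrasts_to_frame(results: Sequence[ContrastResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"outcome": r.outcome, "test": r.test, "statistic": r.statistic,
               "p_value": r.p_value}
        for lv, s in r.groups.items():
            if isinstance(s, dict):
                for k, v in s.items():
                    row[f"{lv}_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_environment(scored: pd.DataFrame) -> dict:
    """Descriptive summary: per-stratum index means +- SD and key proportions
    (share of food-only outlets, share of female retailers).

    These are the quantities that, computed on a surveyed dataset, yield its
    headline descriptive statistics.
    """
    out: dict = {"n": int(len(scored))}
    out["prop_food_only"] = float((scored["shelf_space"] == "food_100").mean())
    out["prop_female"] = float((scored["gender"] == "female").mean())
    out["typology_proportions"] = (
        scored["typology"].value_counts(normalize=True).to_dict()
    )
    per_stratum: dict = {}
    for lv, g in scored.groupby("stratum", observed=True):
        per_stratum[str(lv)] = {
            col: {"mean": float(g[col].mean()), "sd": float(g[col].std(ddof=1))}
            for col in _index_columns(scored)
        }
        per_stratum[str(lv)]["n"] = int(len(g))
    out["by_stratum"] = per_stratum
    return out
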