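"""Fisher exact tests (incl. Monte Carlo r x c), Welch t, Kruskal-Wallis."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from rfeq.contrasts import fisher_exact_rxc, group_contrasts, summarize_environment
from rfeq.indices import score_table
from tests.conftest import make_record


class TestFisher:
    def test_perfect_association_2x2(self):
        res = fisher_exact_rxc([[10, 0], [0, 10]])
        assert res.test == "fisher_exact"
        assert res.p_value < 1e-4

    def test_identical_rows_no_association(self):
        res = fisher_exact_rxc([[7, 3], [7, 3]])
        assert res.p_value == pytest.approx(1.0)

    def test_zero_margin_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero-margin"):
            res = fisher_exact_rxc([[5, 5], [0, 0], [2, 8]])
        assert 0 < res.p_value <= 1

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_rxc([[1.5, 2], [3, 4]])

    def test_mc_matches_full_enumeration_3x2(self):
        """Monte Carlo p within 3 simulation SEs of the exact enumerated p."""
        table = np.array([[8, 2], [3, 7], [5, 5]])
        rows, cols = table.sum(1), table.sum(0)

        def log_prob(t):
            num = sum(math.lgamma(r + 1) for r in rows) + sum(
                math.lgamma(c + 1) for c in cols
            ) - math.lgamma(rows.sum() + 1)
            return num - sum(math.lgamma(v + 1) for v in t.ravel())

        # enumerate all 3x2 tables with these margins (first column free)
        p_obs = log_prob(table)
        total = 0.0
        for a0 in range(rows[0] + 1):
            for a1 in range(rows[1] + 1):
                a2 = cols[0] - a0 - a1
                if not (0 <= a2 <= rows[2]):
                    continue
                t = np.array(
                    [[a0, rows[0] - a0], [a1, rows[1] - a1], [a2, rows[2] - a2]]
                )
                if log_prob(t) <= p_obs + 1e-9:
                    total += math.exp(log_prob(t))
        res = fisher_exact_rxc(table, reps=100_000, seed=42)
        se = res.extra["simulation_se"]
        assert res.p_value == pytest.approx(total, abs=3 * max(se, 1e-4))


def _two_strata_table(catalog, rng, n_r=60, n_u=80, p_r=0.35, p_u=0.25):
    recs = []
    for i in range(n_r + n_u):
        stratum = "rural" if i < n_r else "urban"
        p = p_r if stratum == "rural" else p_u
        present = tuple(c for c in catalog.codes if rng.random() < p)
        recs.append(make_record(catalog, rid=f"r{i}", stratum=stratum,
                                present=present))
    return score_table(recs, catalog)


class TestGroupContrasts:
    def test_identical_strata_null(self, catalog):
        recs = []
        for i in range(10):
            for s in ("rural", "urban"):
                recs.append(
                    make_record(catalog, rid=f"{s}{i}", stratum=s,
                                present=("dglv", "ssb"))
                )
        scored = score_table(recs, catalog)
        for res in group_contrasts(scored, columns=["hrfes"]):
            assert res.statistic == pytest.approx(0.0)
            assert res.p_value == pytest.approx(1.0)

    def test_welch_matches_textbook_formula(self, rng):
        """Welch statistic recomputed by hand from group means/variances."""
        a = rng.normal(2.0, 1.8, 900)
        b = rng.normal(1.8, 2.1, 1200)
        df = pd.DataFrame(
            {
                "stratum": ["rural"] * 900 + ["urban"] * 1200,
                "hrfes": np.concatenate([a, b]),
            }
        )
        res = [r for r in group_contrasts(df, columns=["hrfes"])
               if r.test == "welch_t"][0]
        t_hand = (a.mean() - b.mean()) / math.sqrt(
            a.var(ddof=1) / 900 + b.var(ddof=1) / 1200
        )
        assert res.statistic == pytest.approx(t_hand, rel=1e-12)
        assert res.groups["rural"]["mean"] == pytest.approx(a.mean())
        assert res.groups["rural"]["sd"] == pytest.approx(a.std(ddof=1))

    def test_kruskal_invariant_under_monotone_transform(self, catalog, rng):
        scored = _two_strata_table(catalog, rng)
        kw = [r for r in group_contrasts(scored, columns=["rfeqi"])
              if r.test == "kruskal_wallis"][0]
        transformed = scored.copy()
        transformed["rfeqi"] = np.exp(transformed["rfeqi"] / 3.0) + 5
        kw_t = [r for r in group_contrasts(transformed, columns=["rfeqi"])
                if r.test == "kruskal_wallis"][0]
        assert kw_t.statistic == pytest.approx(kw.statistic, rel=1e-12)
        assert kw_t.p_value == pytest.approx(kw.p_value, rel=1e-12)

    def test_tiny_stratum_rejected(self, catalog):
        recs = [
            make_record(catalog, rid="a", stratum="rural"),
            make_record(catalog, rid="b", stratum="urban"),
            make_record(catalog, rid="c", stratum="urban"),
        ]
        with pytest.raises(ValueError, match="< 2"):
            group_contrasts(score_table(recs, catalog))


class TestSummarize:
    def test_proportions_and_means(self, catalog, rng):
        scored = _two_strata_table(catalog, rng)
        s = summarize_environment(scored)
        assert s["n"] == len(scored)
        assert s["prop_food_only"] == 1.0  # factory default shelf level
        assert s["prop_female"] == 1.0
        assert set(s["by_stratum"]) == {"rural", "urban"}
        assert s["by_stratum"]["rural"]["hrfes"]["mean"] == pytest.approx(
            scored[scored.stratum == "rural"]["hrfes"].mean()
        )
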