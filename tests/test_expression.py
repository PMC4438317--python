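"""RTA, outlier, Indicator Value and rank-sum statistics."""
from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amdscope import expression, mapping, synthetic
from amdscope.expression import ExpressionTable
from amdscope.synthetic import GenomeSpec


def _table(counts: dict, totals: dict | None = None,
           level: str = "KO") -> ExpressionTable:
    """counts: {(feature, genome): (dna, cdna)}."""
    idx = pd.MultiIndex.from_tuples(list(counts), names=["feature", "genome"])
    df = pd.DataFrame(
        {"dna_count": [v[0] for v in counts.values()],
         "cdna_count": [v[1] for v in counts.values()]}, index=idx)
    if totals is None:
        tot = df.groupby(level="genome").sum()
        tot.columns = ["dna_total", "cdna_total"]
    else:
        tot = pd.DataFrame(totals).T
        tot.columns = ["dna_total", "cdna_total"]
        tot.index.name = "genome"
    return ExpressionTable(counts=df, totals=tot, level=level)


@pytest.fixture(scope="module")
def community():
    specs = [GenomeSpec(f"G{i}", 40_000, gc, 3, seed=80 + i)
             for i, gc in enumerate((0.42, 0.58))]
    return synthetic.generate_community(specs, [0.7, 0.3], 10, seed=81)


class TestMapReadsToFeatures:
    def test_gene_read_counted_for_gene(self, community):
        from amdscope.containers import Read, ReadSet
        g = community.gene_models[0]
        seq = community.sequences[g.genome][g.start:g.start + 101]
        reads = ReadSet([Read("r", seq)])
        counts, totals, un = expression.map_reads_to_features(
            reads, community.gene_models, community.sequences)
        assert counts.loc[(g.gene_id, g.genome), "count"] == 1
        assert totals[g.genome] == 1 and un == 0

    def test_intergenic_read_counts_genome_only(self, community):
        from amdscope.containers import Read, ReadSet
        genes = sorted(community.genes_of("G0"), key=lambda g: g.start)
        gap_start = genes[0].end + 10
        assert genes[1].start - gap_start > 150  # a real intergenic window
        seq = community.sequences["G0"][gap_start:gap_start + 101]
        counts, totals, _ = expression.map_reads_to_features(
            ReadSet([Read("r", seq)]), community.gene_models,
            community.sequences)
        assert counts["count"].sum() == 0
        assert totals["G0"] == 1

    def test_counts_match_multinomial_truth(self, community):
        reads, probs = synthetic.simulate_cdna_reads(community, 10_000, seed=82)
        counts, _, un = expression.map_reads_to_features(
            reads, community.gene_models, community.sequences)
        assert un < 50
        n = len(reads)
        for g in community.gene_models:
            p = probs[g.gene_id]
            got = counts.loc[(g.gene_id, g.genome), "count"]
            assert abs(got - n * p) <= 3 * np.sqrt(n * p * (1 - p)) + 3


class TestSharesAndRta:
    def test_share_is_count_over_total(self):
        t = _table({("k1", "g1"): (5, 5)}, totals={"g1": (50, 50)})
        shares, _ = expression.relative_abundances(t)
        assert shares.loc[("k1", "g1"), "dna_share"] == pytest.approx(0.1)

    def test_shares_bounded_by_one(self):
        t = _table({("k1", "g1"): (10, 20), ("k2", "g1"): (30, 20)})
        shares, _ = expression.relative_abundances(t)
        assert shares.groupby(level="genome").sum().le(1 + 1e-12).all().all()

    def test_zero_total_genome_excluded(self):
        t = _table({("k1", "g1"): (5, 5), ("k1", "g2"): (0, 0)})
        with pytest.warns(UserWarning, match="excluded"):
            shares, excluded = expression.relative_abundances(t)
        assert excluded == ["g2"]
        assert "g2" not in shares.index.get_level_values("genome")

    def test_rta_null_and_ratio(self):
        t = _table({("k1", "g1"): (2, 2), ("k2", "g1"): (98, 98)})
        res = expression.rta(t)
        assert res.rta[("k1", "g1")] == pytest.approx(1.0)
        t2 = _table({("k1", "g1"): (2, 4), ("k2", "g1"): (98, 96)})
        res2 = expression.rta(t2)
        assert res2.rta[("k1", "g1")] == pytest.approx((4 / 100) / (2 / 100))

    def test_zero_dna_pseudocount_flagged(self):
        t = _table({("k1", "g1"): (0, 10), ("k2", "g1"): (50, 40)})
        res = expression.rta(t)
        assert res.table.loc[("k1", "g1"), "flag"] == "pseudocount"
        expected = ((10 + 0.5) / 50) / (0.5 / 50)
        assert res.rta[("k1", "g1")] == pytest.approx(expected)

    def test_both_zero_undefined(self):
        t = _table({("k1", "g1"): (0, 0), ("k2", "g1"): (50, 40)})
        res = expression.rta(t)
        assert res.table.loc[("k1", "g1"), "flag"] == "undefined"
        assert np.isnan(res.rta[("k1", "g1")])


# --- independent quantile oracle ------------------------------------------

def _oracle_quartiles(values):
    """Linear-interpolation quartiles, coded independently of numpy."""
    s = sorted(values)
    n = len(s)

    def q(p):
        h = p * (n - 1)
        lo = int(h)
        hi = min(lo + 1, n - 1)
        return s[lo] + (h - lo) * (s[hi] - s[lo])

    return q(0.25), q(0.75)


class TestDetectOutliers:
    def test_single_spike_flagged(self):
        t = _table({(f"k{i}", "g1"): (1, c)
                    for i, c in enumerate([1, 1, 1, 1, 100])})
        flags, _ = expression.detect_outliers(t)
        assert flags["g1"].sum() == 1
        assert flags.loc["k4", "g1"]

    def test_equal_counts_none_flagged(self):
        t = _table({(f"k{i}", "g1"): (1, 7) for i in range(6)})
        flags, _ = expression.detect_outliers(t)
        assert not flags["g1"].any()

    def test_fewer_than_four_features_skipped(self):
        t = _table({("k1", "g1"): (1, 5), ("k2", "g1"): (1, 9)})
        with pytest.warns(UserWarning, match="skipped"):
            flags, skipped = expression.detect_outliers(t)
        assert skipped == ["g1"] and not flags["g1"].any()

    @pytest.mark.parametrize("mode", ["fence", "literal"])
    def test_matches_independent_quantile_oracle(self, mode):
        rng = np.random.default_rng(90)
        for _ in range(20):
            n = int(rng.integers(4, 30))
            counts = rng.poisson(5, size=n)
            t = _table({(f"k{i}", "g"): (1, int(c))
                        for i, c in enumerate(counts)})
            flags, _ = expression.detect_outliers(t, mode=mode)
            q1, q3 = _oracle_quartiles(counts)
            thr = (q3 + 1.5 * (q3 - q1)) if mode == "fence" else 1.5 * (q3 - q1)
            for i, c in enumerate(counts):
                assert flags.loc[f"k{i}", "g"] == (c > thr)


class TestIndicatorValues:
    def test_concentration_in_one_genome(self):
        t = _table({("k1", "g1"): (5, 40), ("k1", "g2"): (5, 0),
                    ("k2", "g1"): (5, 10), ("k2", "g2"): (5, 10)})
        iv = expression.indicator_value(t)
        assert iv.loc["k1", "g1"] == pytest.approx(100.0)
        assert iv.loc["k1", "g2"] == pytest.approx(0.0)

    def test_equal_shares_split_evenly(self):
        counts = {("k1", g): (5, 10) for g in ("g1", "g2", "g3", "g4")}
        counts.update({("k2", g): (5, 30) for g in ("g1", "g2", "g3", "g4")})
        iv = expression.indicator_value(_table(counts))
        assert np.allclose(iv.loc["k1"], 25.0)

    def test_strict_indicator_threshold(self):
        iv = pd.DataFrame({"g1": [50.0, 100.0, 90.0],
                           "g2": [50.0, 0.0, 10.0]},
                          index=["k1", "k2", "k3"])
        iv.index.name, iv.columns.name = "feature", "genome"
        outl = pd.DataFrame({"g1": [True, True, False],
                             "g2": [False, False, False]},
                            index=iv.index, columns=iv.columns)
        res = expression.identify_indicators(outl, iv, threshold=50)
        assert not res.indicator.loc["k1", "g1"]  # exactly 50: excluded
        assert res.indicator.loc["k2", "g1"]      # 100 and outlier
        assert not res.indicator.loc["k3", "g1"]  # high IV, not an outlier

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 50), st.integers(0, 50),
                              st.integers(0, 50)),
                    min_size=2, max_size=8))
    def test_iv_conservation_property(self, rows):
        counts = {}
        for i, (a, b, c) in enumerate(rows):
            counts[(f"k{i}", "g1")] = (1, a)
            counts[(f"k{i}", "g2")] = (1, b)
            counts[(f"k{i}", "g3")] = (1, c)
        if all(a + b + c == 0 for a, b, c in rows):
            return  # all genomes would be excluded
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            iv = expression.indicator_value(_table(counts))
        sums = iv.sum(axis=1)
        for s in sums:
            assert s == pytest.approx(100.0, abs=1e-6) or s == 0.0
        assert ((iv >= 0) & (iv <= 100 + 1e-9)).all().all()


# --- rank-sum ---------------------------------------------------------------

def _exact_ranksum_oracle(x, y):
    """Two-sided p by full enumeration of group assignments (tiny n)."""
    pooled = np.concatenate([x, y])
    n, nx = len(pooled), len(x)
    ranks = pd.Series(pooled).rank().to_numpy()
    w_obs = ranks[:nx].sum()
    mu = nx * (n + 1) / 2
    count = 0
    total = 0
    for comb in itertools.combinations(range(n), nx):
        w = ranks[list(comb)].sum()
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            count += 1
    return count / total


class TestRankSum:
    def test_identical_distributions_high_p(self):
        x = np.arange(10, dtype=float)
        p = expression.ranksum_pvalue(x, x + 0.5)
        assert p > 0.5

    def test_complete_separation_small_p(self):
        x = np.arange(10, dtype=float) + 100
        y = np.arange(30, dtype=float)
        p = expression.ranksum_pvalue(x, y)
        assert p < 0.001

    def test_degenerate_all_equal(self):
        assert expression.ranksum_pvalue([1.0] * 5, [1.0] * 5) == 1.0

    def test_exact_path_matches_enumeration_oracle(self):
        rng = np.random.default_rng(91)
        for _ in range(10):
            x = rng.normal(size=int(rng.integers(3, 6)))
            y = rng.normal(size=int(rng.integers(3, 6)))
            assert expression.ranksum_pvalue(x, y) == pytest.approx(
                _exact_ranksum_oracle(x, y), abs=1e-9)


class TestCompareRta:
    def _rta_frame(self, values: dict) -> pd.DataFrame:
        idx = pd.MultiIndex.from_tuples(list(values),
                                        names=["feature", "genome"])
        return pd.DataFrame({"rta": list(values.values()),
                             "flag": "ok"}, index=idx)

    def test_identical_groups_not_flagged(self):
        vals = {(f"k{i}", g): float(i) for i in range(6)
                for g in ("g1", "g2", "g3")}
        res = expression.compare_rta(
            self._rta_frame(vals), {f"k{i}": "cat" for i in range(6)})
        assert not res["enriched"].any()
        assert (res["p_value"] > 0.5).all()

    def test_dominant_genome_flagged(self):
        vals = {}
        for i in range(10):
            vals[(f"k{i}", "hot")] = 100.0 + i
            for g in ("g1", "g2", "g3"):
                vals[(f"k{i}", g)] = float(i)
        res = expression.compare_rta(
            self._rta_frame(vals), {f"k{i}": "cat" for i in range(10)})
        hot = res[res["genome"] == "hot"].iloc[0]
        assert hot["p_value"] < 0.001 and hot["enriched"]

    def test_degenerate_group_reported(self):
        vals = {("k1", "g1"): 1.0, ("k1", "g2"): 2.0, ("k2", "g2"): 3.0}
        res = expression.compare_rta(self._rta_frame(vals),
                                     {"k1": "cat", "k2": "cat"})
        g1 = res[res["genome"] == "g1"].iloc[0]
        assert np.isnan(g1["p_value"]) and "degenerate" in g1["reason"]


class TestProfilesAndRankings:
    def test_zscore_row_values(self):
        m = pd.DataFrame({"g1": [1.0], "g2": [2.0], "g3": [3.0]},
                         index=["cat"])
        z, flagged = expression.zscore_profile(m)
        np.testing.assert_allclose(
            z.loc["cat"], [-1.2247448, 0.0, 1.2247448], atol=1e-6)
        assert flagged == []

    def test_constant_row_zeroed_and_flagged(self):
        m = pd.DataFrame({"g1": [5.0, 1.0], "g2": [5.0, 2.0]},
                         index=["flat", "var"])
        z, flagged = expression.zscore_profile(m)
        assert flagged == ["flat"]
        assert (z.loc["flat"] == 0).all()
        assert z.loc["var"].mean() == pytest.approx(0.0, abs=1e-9)

    def test_top_expressed_ranks_and_short_input(self):
        t = _table({(f"k{i}", "g1"): (10, 10 * (i + 1)) for i in range(3)})
        res = expression.rta(t)
        with pytest.warns(UserWarning, match="only 3"):
            top = expression.top_expressed(res, t, n=10)
        assert list(top["feature"]) == ["k2", "k1", "k0"]
        assert list(top["rank"]) == [1, 2, 3]

    def test_top_expressed_tie_break_by_cdna_then_id(self):
        t = _table({("a", "g1"): (10, 20), ("b", "g1"): (20, 40),
                    ("c", "g1"): (10, 20), ("d", "g1"): (5, 40)})
        res = expression.rta(t)
        top = expression.top_expressed(res, t, n=4)
        # d has the highest rta; a, b, c tie at rta=1 -> cdna desc, then id
        assert list(top["feature"]) == ["d", "b", "a", "c"]
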