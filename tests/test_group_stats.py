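import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from cestkit.contrast import ContrastMap
from cestkit.group_stats import (ComparisonScheme, StatsError, aggregate_regions,
                                 comparison_suite, omnibus_anova, pairwise_ttest,
                                 summary_table, tier)


# ---- independent brute-force oracles (sums of squares, closed forms) -------

def oracle_pooled_t(a, b):
    na, nb = len(a), len(b)
    va = sum((x - sum(a) / na) ** 2 for x in a) / (na - 1)
    vb = sum((x - sum(b) / nb) ** 2 for x in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    t = (sum(a) / na - sum(b) / nb) / (sp2 * (1 / na + 1 / nb)) ** 0.5
    return t, na + nb - 2


def oracle_welch_df(a, b):
    na, nb = len(a), len(b)
    va = sum((x - sum(a) / na) ** 2 for x in a) / (na - 1)
    vb = sum((x - sum(b) / nb) ** 2 for x in b) / (nb - 1)
    u, v = va / na, vb / nb
    return (u + v) ** 2 / (u**2 / (na - 1) + v**2 / (nb - 1))


def oracle_anova_f(groups):
    allv = [x for g in groups for x in g]
    grand = sum(allv) / len(allv)
    ss_between = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_within = sum((x - sum(g) / len(g)) ** 2 for g in groups for x in g)
    df_b, df_w = len(groups) - 1, len(allv) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


class TestAggregateRegions:
    def _map(self, values, mask=None):
        values = np.asarray(values, dtype=float)
        mask = np.isfinite(values) if mask is None else mask
        return ContrastMap(values=values, mask=mask, pool="glutamate",
                           mode="analytic")

    def test_constant_map(self):
        labels = np.array([[1, 1], [2, 2]])
        rows = aggregate_regions(self._map(np.full((2, 2), 3.0)), labels,
                                 {1: "cortex", 2: "thalamus"}, "s1", "baseline")
        assert {r["contrast"] for r in rows} == {3.0}

    def test_four_voxel_mean(self):
        labels = np.array([[1, 1], [1, 1]])
        rows = aggregate_regions(self._map([[1.0, 2.0], [3.0, 4.0]]), labels,
                                 {1: "cortex"}, "s1", "baseline")
        assert rows[0]["contrast"] == 2.5

    def test_fully_masked_region_missing(self):
        labels = np.array([[1, 1], [2, 2]])
        values = np.array([[np.nan, np.nan], [1.0, 1.0]])
        rows = aggregate_regions(self._map(values), labels,
                                 {1: "cortex", 2: "thalamus"}, "s1", "baseline")
        assert [r["region"] for r in rows] == ["thalamus"]

    def test_unknown_label_error(self):
        labels = np.array([[1, 7], [1, 1]])
        with pytest.raises(StatsError, match="registry"):
            aggregate_regions(self._map(np.ones((2, 2))), labels, {1: "cortex"},
                              "s1", "baseline")


class TestAnova:
    def test_worked_example_f_300(self):
        groups = {"a": [0, 1, 2], "b": [10, 11, 12], "c": [20, 21, 22]}
        rep = omnibus_anova(groups)
        assert rep.statistic == pytest.approx(300.0, rel=1e-12)
        assert rep.df == (2.0, 6.0)
        assert rep.p < 0.0001 and rep.tier == "****"

    def test_equal_means_f_zero(self):
        rep = omnibus_anova({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert rep.statistic == pytest.approx(0.0, abs=1e-14)
        assert rep.p == pytest.approx(1.0)

    def test_constant_groups_degenerate(self):
        rep = omnibus_anova({"a": [5, 5], "b": [5, 5]})
        assert rep.variant == "degenerate"
        assert np.isnan(rep.p)

    def test_small_arm_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            rep = omnibus_anova({"a": [1, 2, 3], "b": [4, 5, 6], "c": [9]})
        assert rep.df == (1.0, 4.0)


class TestPairwise:
    def test_identical_groups(self):
        rep = pairwise_ttest([1, 2, 3], [1, 2, 3], "pooled")
        assert rep.statistic == pytest.approx(0.0, abs=1e-14)
        assert rep.p == pytest.approx(1.0)

    def test_hand_computed_pooled(self):
        rep = pairwise_ttest([1, 2, 3], [4, 5, 6], "pooled")
        assert rep.statistic == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), rel=1e-12)
        assert rep.statistic == pytest.approx(-3.674, abs=5e-4)
        assert rep.df == 4.0

    def test_welch_df_below_pooled(self):
        rep = pairwise_ttest([1, 2, 3, 4, 5], [10, 20], "welch")
        assert rep.df < 5
        assert rep.df == pytest.approx(oracle_welch_df([1, 2, 3, 4, 5], [10, 20]),
                                       rel=1e-10)

    def test_zero_variance_degenerate(self):
        rep = pairwise_ttest([2, 2, 2], [2, 2, 2], "pooled")
        assert rep.variant == "degenerate"

    def test_unknown_variant_rejected(self):
        with pytest.raises(StatsError):
            pairwise_ttest([1, 2], [3, 4], "bayes")

    def test_tiny_group_rejected(self):
        with pytest.raises(StatsError):
            pairwise_ttest([1], [2, 3], "pooled")


def test_statistics_match_bruteforce_oracle():
    """Pooled t, Welch df and one-way F agree with direct sums of squares."""
    rng = np.random.default_rng(11)
    for _ in range(20):
        sizes = rng.integers(3, 9, size=3)
        groups = [list(rng.normal(rng.uniform(-2, 2), 1.0, n)) for n in sizes]
        t_rep = pairwise_ttest(groups[0], groups[1], "pooled")
        t_or, df_or = oracle_pooled_t(groups[0], groups[1])
        assert t_rep.statistic == pytest.approx(t_or, abs=1e-10)
        assert t_rep.df == df_or
        w_rep = pairwise_ttest(groups[0], groups[1], "welch")
        assert w_rep.df == pytest.approx(oracle_welch_df(groups[0], groups[1]),
                                         abs=1e-10)
        a_rep = omnibus_anova({f"g{i}": g for i, g in enumerate(groups)})
        assert a_rep.statistic == pytest.approx(oracle_anova_f(groups), abs=1e-10)


class TestTier:
    @pytest.mark.parametrize("p,label", [
        (0.04, "*"), (0.0006, "***"), (0.5, "ns"),
        (0.0, "****"), (0.00009, "****"), (0.0001, "***"), (0.001, "**"),
        (0.01, "*"), (0.05, "#"), (0.09999, "#"), (0.1, "ns"), (1.0, "ns"),
    ])
    def test_bins(self, p, label):
        assert tier(p) == label

    def test_domain_error(self):
        for bad in (-0.01, 1.5, np.nan):
            with pytest.raises(ValueError):
                tier(bad)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(0, 1, allow_nan=False))
    def test_total_function_on_unit_interval(self, p):
        assert tier(p) in {"****", "***", "**", "*", "#", "ns"}


def _full_table(rng, effect=1.0):
    rows = []
    n_per = {"baseline": 5, "wk6": 5, "wk12_vehicle": 4, "wk12_art": 3}
    for arm, n in n_per.items():
        scale = effect if arm == "wk12_vehicle" else 1.0
        for k in range(n):
            for region in ("cortex", "thalamus"):
                for pool in ("glutamate", "creatine"):
                    rows.append({"subject": f"{arm}{k}", "arm": arm,
                                 "region": region, "pool": pool,
                                 "contrast": rng.normal(1.0 * scale, 0.05)})
    return pd.DataFrame(rows)


class TestComparisonSuite:
    def test_structure_one_anova_three_ttests(self):
        table = _full_table(np.random.default_rng(0))
        reports, _ = comparison_suite(table)
        for (region, pool) in [("cortex", "glutamate"), ("thalamus", "creatine")]:
            sub = [r for r in reports if r.region == region and r.pool == pool]
            assert sum(r.variant == "anova" for r in sub) == 1
            assert sum(r.variant in ("pooled", "welch") for r in sub) == 3
        variants = {r.comparison: r.variant for r in reports if r.variant != "anova"}
        assert variants["baseline vs wk6"] == "pooled"
        assert variants["baseline vs wk12_vehicle"] == "welch"
        assert variants["wk12_art vs wk12_vehicle"] == "pooled"

    def test_missing_arm_skipped_with_warning(self):
        table = _full_table(np.random.default_rng(0))
        table = table[table["arm"] != "wk12_art"]
        with pytest.warns(UserWarning, match="skipped"):
            reports, _ = comparison_suite(table)
        assert not any("wk12_art" in r.comparison for r in reports)

    def test_sem_column(self):
        table = pd.DataFrame([
            {"subject": f"s{i}", "arm": "baseline", "region": "cortex",
             "pool": "glutamate", "contrast": v} for i, v in enumerate([2, 4, 6])])
        summary = summary_table(table)
        assert summary["sem"].iloc[0] == pytest.approx(2 / np.sqrt(3))
        assert summary["mean"].iloc[0] == pytest.approx(4.0)

    def test_nonfinite_contrast_rejected(self):
        table = _full_table(np.random.default_rng(0))
        table.loc[0, "contrast"] = np.nan
        with pytest.raises(StatsError):
            comparison_suite(table)

    def test_holm_never_decreases_p(self):
        table = _full_table(np.random.default_rng(2), effect=0.8)
        plain, _ = comparison_suite(table)
        holm, _ = comparison_suite(table, ComparisonScheme(holm=True))
        for r0, r1 in zip(plain, holm):
            if r1.variant != "degenerate":
                assert r1.p >= r0.p - 1e-15
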