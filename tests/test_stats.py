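"""Corpus statistics: distributions, residuals, tests, odds ratios."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from oncorel import (
    ContingencyTable,
    Corpus,
    chi_square_test,
    contingency,
    odds_ratio,
    pearson_residuals,
    percent_round_half_up,
    rule_distribution,
    stratified_independence_test,
    truncate_1dp,
    value_distribution,
)
from oncorel.catalog import CCS, CGE, IGE, PT
from oncorel.simulate import GeneratorConfig, default_config_from_tables, generate_corpus
from oncorel.stats import format_p_value

from conftest import make_unit


# Published reference counts, used as desk-scale inputs throughout.
CGE_CCS = ContingencyTable.from_counts(
    [[318, 45, 204], [79, 76, 99]],
    ["increased", "decreased"],
    ["normal->cancer", "cancer->normal", "unidentifiable"],
    row_concept=CGE,
    col_concept=CCS,
)
PT_CCS = ContingencyTable.from_counts(
    [[311, 43], [86, 78]],
    ["observation", "causality"],
    ["normal->cancer", "cancer->normal"],
    row_concept=PT,
    col_concept=CCS,
)


class TestPercentFormatting:
    @pytest.mark.parametrize(
        "count, denom, expected",
        [(567, 821, 69), (254, 821, 31), (2, 518, 0), (212, 518, 41), (304, 518, 59), (1, 2, 50)],
    )
    def test_round_half_up(self, count, denom, expected):
        assert percent_round_half_up(count, denom) == expected

    def test_half_rounds_up(self):
        assert percent_round_half_up(1, 200) == 1  # 0.5% -> 1

    def test_truncate_not_round(self):
        assert truncate_1dp(6.559) == 6.5
        assert truncate_1dp(7.867) == 7.8

    def test_p_value_floor(self):
        assert format_p_value(1e-20) == "<2.2e-16"
        assert format_p_value(0.32) == "0.32"


class TestValueDistribution:
    def test_single_value_corpus(self):
        corpus = Corpus(units=[make_unit(unit_id=f"u{i}") for i in range(4)])
        (dist,) = value_distribution(corpus, CGE)
        assert dist.counts["increased"] == 4 and dist.percentages["increased"] == 100
        assert dist.percentages["decreased"] == 0

    def test_not_annotated_excluded_from_denominator(self):
        units = [
            make_unit("a", ccs="normal->cancer"),
            make_unit("b", ccs="unidentifiable"),
            make_unit("c", ccs="cancer->normal", ige="unidentifiable", pt="causality",
                      cge="decreased"),
        ]
        (dist,) = value_distribution(Corpus(units=units), IGE)
        assert dist.denominator == 2  # the unidentifiable-CCS unit carries no IGE

    def test_grouping_by_cancer_type(self):
        units = [
            make_unit("a", cancer_type="prostate"),
            make_unit("b", cancer_type="breast", cge="decreased"),
        ]
        dists = value_distribution(Corpus(units=units), CGE, group_by_cancer_type=True)
        assert [d.group for d in dists] == ["breast", "prostate", "Total"]
        total = dists[-1]
        assert total.counts == {"increased": 1, "decreased": 1}

    def test_percentages_sum_to_about_100(self):
        corpus = generate_corpus(default_config_from_tables(n_units=2000, seed=3))
        for concept in (CGE, CCS, IGE, PT):
            for dist in value_distribution(corpus, concept, group_by_cancer_type=True):
                assert abs(sum(dist.percentages.values()) - 100) <= 2

    def test_unknown_concept_raises(self):
        with pytest.raises(ValueError):
            value_distribution(Corpus(units=[make_unit()]), "XYZ")


class TestContingency:
    def test_counts_match_independent_tally(self):
        corpus = generate_corpus(default_config_from_tables(n_units=3000, seed=11))
        table = contingency(corpus, CGE, CCS)
        tally = {}
        for u in corpus:
            tally[(u.cge, u.ccs)] = tally.get((u.cge, u.ccs), 0) + 1
        for i, rl in enumerate(table.row_labels):
            for j, cl in enumerate(table.col_labels):
                assert table.observed[i, j] == tally.get((rl, cl), 0)
        assert table.observed.sum() == len(corpus)

    def test_never_observed_values_dropped(self):
        corpus = generate_corpus(default_config_from_tables(n_units=500, seed=2))
        table = contingency(corpus, CGE, CCS)
        assert "normal->normal" not in table.col_labels
        assert "cancer->cancer" not in table.col_labels

    def test_ige_requires_ccs_filter(self):
        corpus = generate_corpus(default_config_from_tables(n_units=100, seed=1))
        with pytest.raises(ValueError, match="ccs_filter"):
            contingency(corpus, IGE, CCS)

    def test_marginal_invariants(self):
        table = CGE_CCS
        expected = table.expected
        assert expected.sum() == pytest.approx(table.n)
        assert np.allclose((table.observed - expected).sum(axis=1), 0)


class TestPearsonResiduals:
    def test_reference_cells(self):
        res = pearson_residuals(CGE_CCS)
        assert res[0, 0] == pytest.approx(2.65, abs=0.005)  # increased, normal->cancer
        assert res[1, 1] == pytest.approx(6.30, abs=0.005)  # decreased, cancer->normal

    def test_uniform_table_has_zero_residuals(self):
        table = ContingencyTable.from_counts([[10, 10], [10, 10]], ["a", "b"], ["x", "y"])
        assert np.allclose(pearson_residuals(table), 0)

    def test_zero_marginal_raises_with_label(self):
        table = ContingencyTable.from_counts([[5, 0], [3, 0]], ["a", "b"], ["x", "y"])
        with pytest.raises(ValueError, match="'y'"):
            pearson_residuals(table)


class TestChiSquare:
    def test_statistic_is_sum_of_squared_residuals(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            counts = rng.integers(1, 30, size=(2, 3))
            table = ContingencyTable.from_counts(counts, ["a", "b"], ["x", "y", "z"])
            res = chi_square_test(table)
            assert res.statistic == pytest.approx(float((pearson_residuals(table) ** 2).sum()))

    def test_agrees_with_scipy_oracle(self):
        result = chi_square_test(CGE_CCS)
        stat, p, df, _ = chi2_contingency(CGE_CCS.observed, correction=False)
        assert result.statistic == pytest.approx(stat)
        assert result.p_value == pytest.approx(p)
        assert result.degrees_of_freedom == df == 2

    def test_reference_table_is_overwhelmingly_significant(self):
        assert chi_square_test(CGE_CCS).p_value < 2.2e-16

    def test_independent_table_gives_p_one(self):
        table = ContingencyTable.from_counts([[10, 10], [10, 10]], ["a", "b"], ["x", "y"])
        result = chi_square_test(table)
        assert result.statistic == 0 and result.p_value == pytest.approx(1.0)

    def test_nominal_type_one_error_on_independent_draws(self):
        rng = np.random.default_rng(42)
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            rows = rng.multinomial(200, [0.25, 0.25, 0.25, 0.25]).reshape(2, 2)
            # independent margins: draw cell counts from a product model
            p_r, p_c = 0.6, 0.3
            probs = np.outer([p_r, 1 - p_r], [p_c, 1 - p_c]).ravel()
            counts = rng.multinomial(200, probs).reshape(2, 2)
            table = ContingencyTable.from_counts(counts, ["a", "b"], ["x", "y"])
            if chi_square_test(table).p_value < 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_rep <= 0.09


class TestOddsRatio:
    def test_reference_pt_ccs(self):
        assert truncate_1dp(odds_ratio(PT_CCS)) == 6.5

    def test_reference_pt_ige_restricted(self):
        table = ContingencyTable.from_counts(
            [[191, 163], [21, 141]], ["observation", "causality"], ["unchanged", "unidentifiable"]
        )
        assert truncate_1dp(odds_ratio(table)) == 7.8

    def test_proportional_rows_give_one(self):
        table = ContingencyTable.from_counts([[10, 20], [30, 60]], ["a", "b"], ["x", "y"])
        assert odds_ratio(table) == pytest.approx(1.0)

    def test_row_swap_inverts(self):
        assert odds_ratio(PT_CCS, rows=("causality", "observation")) == pytest.approx(
            1 / odds_ratio(PT_CCS)
        )

    def test_zero_cell_requires_haldane(self):
        table = ContingencyTable.from_counts([[5, 0], [3, 2]], ["a", "b"], ["x", "y"])
        with pytest.raises(ZeroDivisionError):
            odds_ratio(table)
        assert odds_ratio(table, haldane=True) > 1


class TestStratifiedIndependence:
    def test_identical_independent_strata_give_p_one(self):
        units = []
        i = 0
        for ccs in ("normal->cancer", "cancer->normal"):
            for cge in ("increased", "decreased"):
                for pt in ("observation", "causality"):
                    for _ in range(20):
                        units.append(
                            make_unit(f"s{i}", cge=cge, ccs=ccs, ige="unidentifiable", pt=pt)
                        )
                        i += 1
        result = stratified_independence_test(
            Corpus(units=units), CGE, PT, stratify_by=("normal->cancer", "cancer->normal")
        )
        assert result.p_value == pytest.approx(1.0)
        assert result.method == "cochran-mantel-haenszel"

    def test_type_one_error_calibrated_under_conditional_independence(self):
        # generator samples PT independently of CGE given CCS, so the CMH
        # null holds by construction
        rejections = 0
        n_rep = 100
        for rep in range(n_rep):
            corpus = generate_corpus(default_config_from_tables(n_units=1500, seed=10_000 + rep))
            result = stratified_independence_test(
                corpus, CGE, PT, stratify_by=("normal->cancer", "cancer->normal")
            )
            if result.p_value < 0.05:
                rejections += 1
        assert 0.005 <= rejections / n_rep <= 0.12

    def test_detects_strong_dependence(self):
        units = []
        i = 0
        for ccs in ("normal->cancer", "cancer->normal"):
            for _ in range(60):
                units.append(make_unit(f"d{i}", cge="increased", ccs=ccs,
                                       ige="unidentifiable", pt="observation"))
                i += 1
                units.append(make_unit(f"d{i}", cge="decreased", ccs=ccs,
                                       ige="unidentifiable", pt="causality"))
                i += 1
            for _ in range(6):
                units.append(make_unit(f"d{i}", cge="increased", ccs=ccs,
                                       ige="unidentifiable", pt="causality"))
                i += 1
                units.append(make_unit(f"d{i}", cge="decreased", ccs=ccs,
                                       ige="unidentifiable", pt="observation"))
                i += 1
        result = stratified_independence_test(
            Corpus(units=units), CGE, PT, stratify_by=("normal->cancer", "cancer->normal")
        )
        assert result.p_value < 0.01


class TestRuleDistribution:
    def test_counts_match_unitwise_tally(self):
        from oncorel.rules import classify_unit

        corpus = generate_corpus(default_config_from_tables(n_units=2000, seed=5))
        dist = rule_distribution(corpus)
        tally = {}
        for u in corpus:
            rid = classify_unit(u).rule_id
            key = rid if rid is not None else "no_rule"
            tally[key] = tally.get(key, 0) + 1
        for key in list(range(1, 11)) + ["no_rule"]:
            assert dist.rule_counts["Total"][key] == tally.get(key, 0)
        assert dist.totals() == len(corpus)

    def test_empty_corpus_all_zero(self):
        dist = rule_distribution(Corpus())
        assert all(v == 0 for v in dist.rule_counts["Total"].values())

    def test_class_shares_sum_to_about_100(self):
        corpus = generate_corpus(default_config_from_tables(n_units=2000, seed=6))
        dist = rule_distribution(corpus)
        shares = [dist.class_percent(c) for c in dist.class_counts["Total"]]
        assert abs(sum(shares) - 100) <= 2
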