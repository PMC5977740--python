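"""Validity analytics: preprocessing, correlations, nested regression."""

import numpy as np
import pandas as pd
import pytest

from foodmats.errors import DomainError, UndefinedStatisticError
from foodmats.synthetic import GeneratorParams, generate_study
from foodmats.validity import (
    PipelineConfig, collinearity_screen, correlations, run_validity_pipeline,
    sequential_regression, truncate_outliers, weekly_least_healthy_sales,
)
from oracles import f_change_ss, partial_corr_residuals


class TestTruncation:
    def test_no_outliers_unchanged(self):
        values = [1.0, 2.0, 3.0, 4.0, 5.0]
        out, log = truncate_outliers(values)
        assert list(out) == values and log == []

    def test_outlier_replaced_one_unit_above_next_closest(self):
        # 100 lies beyond mean + 3 SD of the full sample; next closest inside
        # value is 0, so the replacement is 1
        values = [0.0] * 10 + [100.0]
        out, log = truncate_outliers(values)
        assert out[-1] == 1.0
        assert log[0].original == 100.0 and log[0].replacement == 1.0

    def test_sd_includes_the_outlier(self):
        # with the outlier inflating the SD, 1000 is only ~1.8 SDs out at n=5
        out, log = truncate_outliers([1.0, 2.0, 3.0, 4.0, 1000.0])
        assert list(out) == [1.0, 2.0, 3.0, 4.0, 1000.0] and log == []

    def test_tied_outliers_replaced_identically(self):
        values = [0.0] * 20 + [200.0, 200.0]
        out, log = truncate_outliers(values)
        assert out[-1] == out[-2] == 1.0
        assert len(log) == 2

    def test_low_side_truncation(self):
        values = [0.0] * 10 + [-100.0]
        out, _ = truncate_outliers(values)
        assert out[-1] == -1.0

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            values = rng.normal(size=30)
            values[0] += rng.choice([0, 40])
            once, _ = truncate_outliers(values)
            twice, log = truncate_outliers(once)
            assert np.array_equal(once, twice) and log == []

    def test_needs_three_values(self):
        with pytest.raises(DomainError):
            truncate_outliers([1.0, 2.0])


class TestWeeklySales:
    def make_rows(self, rows):
        return pd.DataFrame(rows, columns=["item", "channel", "dollars"])

    def test_two_weeks_halved(self):
        rows = self.make_rows([("cola", "concession", 120.0),
                               ("chips", "concession", 80.0)])
        result = weekly_least_healthy_sales(rows)
        assert result.weekly["concession"] == 100.0

    def test_most_healthy_items_contribute_zero(self):
        rows = self.make_rows([("bottled water", "vending", 300.0),
                               ("apple", "vending", 50.0)])
        assert weekly_least_healthy_sales(rows).weekly["vending"] == 0.0

    def test_unclassifiable_row_flags_channel(self):
        rows = self.make_rows([("cola", "concession", 100.0),
                               ("misc item #4", "vending", 60.0)])
        result = weekly_least_healthy_sales(rows)
        assert result.excluded_channels == ["vending"]
        assert result.unclassified_rows == [1]
        assert np.isnan(result.weekly["vending"])
        assert result.weekly["concession"] == 50.0

    def test_unknown_channel_rejected(self):
        rows = self.make_rows([("cola", "kiosk", 10.0)])
        with pytest.raises(DomainError):
            weekly_least_healthy_sales(rows)


class TestCorrelations:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        result = correlations(x, 2 * x)
        assert result.pearson_r == pytest.approx(1.0)
        assert result.spearman_rho == pytest.approx(1.0)

    def test_partial_without_controls_equals_pearson(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=12), rng.normal(size=12)
        result = correlations(x, y)
        assert result.partial_r == pytest.approx(result.pearson_r)
        assert result.partial_p == pytest.approx(result.pearson_p)

    def test_partial_equals_residual_correlation(self):
        rng = np.random.default_rng(1)
        controls = pd.DataFrame({"c1": rng.normal(size=12),
                                 "c2": rng.normal(size=12)})
        x = controls["c1"] * 2 + rng.normal(size=12)
        y = controls["c2"] - x * 0.5 + rng.normal(size=12)
        result = correlations(x, y, controls)
        oracle = partial_corr_residuals(x, y, controls.to_numpy())
        assert result.partial_r == pytest.approx(oracle, abs=1e-10)

    def test_constant_input_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            correlations([1.0] * 8, list(range(8)))


class TestSequentialRegression:
    def test_outcome_linear_in_block1(self):
        rng = np.random.default_rng(2)
        block1 = pd.DataFrame({"size": rng.normal(size=20)})
        block2 = pd.DataFrame({"score": rng.normal(size=20)})
        y = 3 * block1["size"] + 1
        report = sequential_regression(y, block1, block2)
        assert report.models[0].r2 == pytest.approx(1.0)
        assert report.models[1].dr2 == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_blocks_add_their_marginal_r2(self):
        n = 32
        t = np.arange(n)
        a = np.where(t % 2 == 0, 1.0, -1.0)
        b = np.where((t // 2) % 2 == 0, 1.0, -1.0)  # orthogonal to a
        y = a + 0.5 * b
        report = sequential_regression(y, pd.DataFrame({"a": a}),
                                       pd.DataFrame({"b": b}))
        marginal = sequential_regression(y, pd.DataFrame({"b": b}),
                                         pd.DataFrame({"a": a})).models[0].r2
        assert report.models[1].dr2 == pytest.approx(marginal, abs=1e-10)

    def test_f_change_matches_sum_of_squares_oracle(self):
        rng = np.random.default_rng(3)
        block1 = pd.DataFrame({"c1": rng.normal(size=20), "c2": rng.normal(size=20)})
        block2 = pd.DataFrame({"x": rng.normal(size=20)})
        y = block1["c1"] + 0.8 * block2["x"] + rng.normal(size=20)
        report = sequential_regression(y, block1, block2)
        oracle = f_change_ss(y, block1.to_numpy(), block2.to_numpy())
        assert report.models[1].f_change == pytest.approx(oracle, abs=1e-9)

    def test_nested_r2_monotone(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            block1 = pd.DataFrame({"a": rng.normal(size=15)})
            block2 = pd.DataFrame({"b": rng.normal(size=15)})
            y = rng.normal(size=15)
            report = sequential_regression(y, block1, block2)
            assert report.models[1].r2 >= report.models[0].r2 - 1e-12
            assert report.models[1].dr2 >= -1e-12

    def test_rank_deficient_design_names_columns(self):
        x = np.arange(12.0)
        block1 = pd.DataFrame({"a": x, "b": 2 * x})
        block2 = pd.DataFrame({"c": np.random.default_rng(0).normal(size=12)})
        with pytest.raises(DomainError, match="a~b"):
            sequential_regression(np.random.default_rng(1).normal(size=12),
                                  block1, block2)

    def test_standardized_betas_bounded_for_single_predictor(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=25)
        y = 2 * x + rng.normal(size=25)
        report = sequential_regression(y, pd.DataFrame({"x": x}),
                                       pd.DataFrame({"z": rng.normal(size=25)}))
        beta = report.models[0].betas["x"]
        r = np.corrcoef(x, y)[0, 1]
        assert beta == pytest.approx(r, abs=1e-10)  # single standardized predictor


class TestCollinearityScreen:
    def test_uncorrelated_predictors_unflagged(self):
        rng = np.random.default_rng(6)
        predictors = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        assert collinearity_screen(predictors, rng.normal(size=30)) == []

    def test_duplicated_column_flagged_with_unit_r(self):
        x = np.random.default_rng(7).normal(size=20)
        predictors = pd.DataFrame({"a": x, "b": x})
        flags = collinearity_screen(predictors, np.random.default_rng(8).normal(size=20))
        assert len(flags) == 1 and flags[0].r == pytest.approx(1.0)

    def test_non_predictive_member_recommended_for_drop(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=40)
        b = a + rng.normal(scale=0.1, size=40)  # collinear with a
        y = 2 * a + rng.normal(scale=0.5, size=40)
        # make b useless for y beyond its overlap with a: add pure noise copy
        c = rng.normal(size=40)
        predictors = pd.DataFrame({"a": a, "b": b, "c": c})
        flags = collinearity_screen(predictors, y)
        assert flags and flags[0].pair == ("a", "b")
        # both correlate with y through a; the weaker one is recommended
        assert flags[0].drop in ("a", "b")


@pytest.fixture(scope="module")
def coupled_study():
    params = GeneratorParams(seed=20)
    _, outcomes = generate_study(params)
    return outcomes


class TestPipeline:
    def test_coupled_study_recovers_positive_associations(self, coupled_study):
        report = run_validity_pipeline(coupled_study)
        food = report.sponsorship["food"]
        assert food.partial_r > 0 and food.partial_p < 0.05
        model2 = report.regressions["concession"]["report"].models[1]
        assert model2.dr2 > 0 and model2.p_change < 0.05

    def test_null_coupling_gives_small_dr2(self):
        params = GeneratorParams(seed=21, beta_sponsorship=0.0,
                                 gamma_score_concession=0.0,
                                 gamma_score_vending=0.0)
        _, outcomes = generate_study(params)
        report = run_validity_pipeline(outcomes)
        model2 = report.regressions["concession"]["report"].models[1]
        assert model2.dr2 < 0.15

    def test_all_sponsorship_missing_skips_section(self, coupled_study):
        outcomes = coupled_study.copy()
        outcomes["food_sponsorship"] = np.nan
        outcomes["total_sponsorship"] = np.nan
        report = run_validity_pipeline(outcomes)
        assert report.sponsorship == {}
        assert any("sponsorship section skipped" in line for line in report.log)

    def test_missing_sales_column_skips_regression_only(self, coupled_study):
        outcomes = coupled_study.drop(columns=["sales_least_vending"])
        report = run_validity_pipeline(outcomes)
        assert "vending" not in report.regressions
        assert "concession" in report.regressions
        assert report.sponsorship  # correlations still run

    def test_too_few_sites_rejected(self, coupled_study):
        with pytest.raises(DomainError, match="at least 10"):
            run_validity_pipeline(coupled_study.head(3))

    def test_missing_data_t_tests_reported(self, coupled_study):
        report = run_validity_pipeline(coupled_study)
        t = report.missing_data_tests["food_sponsorship"]
        assert t["n_present"] + t["n_missing"] == len(coupled_study)
        assert np.isfinite(t["p"])

    def test_report_serializes_to_plain_dict(self, coupled_study):
        import json
        payload = run_validity_pipeline(coupled_study).to_dict()
        json.dumps(payload, default=str)  # must not raise
        assert payload["n_sites"] == len(coupled_study)
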