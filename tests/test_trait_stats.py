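import numpy as np
import pandas as pd
import pytest

from lossaversion.prospect_model import ChoiceDataset
from lossaversion.trait_stats import (IDENTITY_BIS11_MAP, load_bis11_map,
                                      one_sample_t, partial_r, pearson_r,
                                      risky_percentage, robust_regression,
                                      score_bis, score_dgs)


class TestQuestionnaireScoring:
    @pytest.mark.parametrize("items,total", [
        ([1] * 7, 7),
        ([5] * 7, 35),
        ([1, 2, 3, 4, 5, 1, 2], 18),
    ])
    def test_dgs_totals(self, items, total):
        assert score_dgs(items) == total

    def test_dgs_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            score_dgs([1, 2, 3, 4, 5, 6, 1])
        with pytest.raises(ValueError):
            score_dgs([1] * 6)

    def test_bis_raw_sum_bounds(self):
        assert score_bis([1] * 30, IDENTITY_BIS11_MAP)["total"] == 30
        assert score_bis([5] * 30, IDENTITY_BIS11_MAP)["total"] == 150

    def test_bis_subscales_add_to_total(self):
        rng = np.random.default_rng(0)
        items = rng.integers(1, 6, 30)
        out = score_bis(items)
        assert out["cognitive"] + out["motor"] + out["nonplanning"] == out["total"]

    def test_bis_reverse_scoring_applied(self):
        m = load_bis11_map()
        items = [1] * 30
        out = score_bis(items, m)
        # reversed items score 6 - 1 = 5 each
        assert out["total"] == (30 - len(m["reversed"])) + 5 * len(m["reversed"])

    def test_bis_rejects_bad_input(self):
        with pytest.raises(ValueError):
            score_bis([1] * 29)
        with pytest.raises(ValueError):
            score_bis([0] + [1] * 29)


class TestRiskyPercentage:
    def _ds(self, rows):
        return ChoiceDataset(pd.DataFrame(rows, columns=[
            "subject_id", "trial_index", "condition",
            "gamble_out1", "gamble_out2", "sure", "choice"]))

    def test_all_gamble_is_100(self):
        ds = self._ds([(0, i, "mixed", 10.0, -5.0, 0.0, 1.0) for i in range(4)])
        assert risky_percentage(ds) == 100.0

    def test_half_gamble_is_50(self):
        rows = [(0, i, "mixed", 10.0, -5.0, 0.0, float(i < 72))
                for i in range(144)]
        assert risky_percentage(self._ds(rows), "mixed") == 50.0

    def test_unanswered_condition_is_missing_not_zero(self):
        rows = [(0, 0, "gain", 0.0, 12.0, 6.0, np.nan),
                (0, 1, "mixed", 10.0, -5.0, 0.0, 1.0)]
        assert np.isnan(risky_percentage(self._ds(rows), "gain"))

    def test_catch_trials_excluded(self):
        rows = [(0, 0, "mixed", 10.0, -5.0, 0.0, 1.0),
                (0, 1, "catch_gain", 0.0, 10.0, 10.0, 0.0)]
        assert risky_percentage(self._ds(rows)) == 100.0


class TestPearson:
    def test_perfect_linear(self):
        assert pearson_r([1, 2, 3, 4], [3, 5, 7, 9]).r == pytest.approx(1.0)

    def test_perfect_negative(self):
        assert pearson_r([1, 2, 3], [3, 2, 1]).r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        res = pearson_r([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.r == pytest.approx(0.8)
        assert res.t == pytest.approx(0.8 * np.sqrt(2 / (1 - 0.64)))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestPartial:
    def test_no_covariates_equals_pearson(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal((2, 30))
        assert partial_r(x, y).r == pearson_r(x, y).r

    def test_unrelated_covariate_changes_little(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(500)
        y = 0.6 * x + rng.standard_normal(500)
        c = rng.standard_normal(500)
        assert partial_r(x, y, c).r == pytest.approx(pearson_r(x, y).r, abs=0.05)

    def test_outcome_equal_to_covariate_partials_to_zero(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(40)
        c = rng.standard_normal(40)
        assert abs(partial_r(x, c, c).r) < 1e-8

    def test_matches_residual_oracle_exactly(self):
        """Six-point worked instance against explicit residual regression."""
        x = np.array([1.0, 2.0, 4.0, 5.0, 7.0, 8.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 9.0, 7.0])
        c = np.array([1.0, 1.0, 2.0, 3.0, 5.0, 8.0])
        res = partial_r(x, y, c)
        X = np.column_stack([np.ones(6), c])
        rx = x - X @ np.linalg.solve(X.T @ X, X.T @ x)
        ry = y - X @ np.linalg.solve(X.T @ X, X.T @ y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert res.r == pytest.approx(oracle, abs=1e-10)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.standard_normal((25, 3)), columns=["x", "y", "c"])
        ours = partial_r(df["x"], df["y"], df[["c"]])
        theirs = pg.partial_corr(df, x="x", y="y", covar="c")
        pcol = "p_val" if "p_val" in theirs.columns else "p-val"
        assert ours.r == pytest.approx(float(theirs["r"].iloc[0]), abs=1e-10)
        assert ours.p == pytest.approx(float(theirs[pcol].iloc[0]), abs=1e-8)

    def test_regression_formulation_matches_partial_t(self):
        from lossaversion.trait_stats import regression_control

        rng = np.random.default_rng(7)
        x, c = rng.standard_normal((2, 30))
        y = 0.5 * x + 0.4 * c + rng.standard_normal(30)
        reg = regression_control(x, y, c)
        part = partial_r(x, y, c)
        assert reg["t"] == pytest.approx(part.t, abs=1e-8)
        assert reg["p"] == pytest.approx(part.p, abs=1e-8)

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(6)
        x, y, c = rng.standard_normal((3, 20))
        with pytest.raises(ValueError):
            partial_r(x, y, np.column_stack([c, 2 * c]))


class TestRobustRegression:
    def test_clean_data_matches_ols(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(60)
        y = 1.0 + 2.0 * x + 0.3 * rng.standard_normal(60)
        fit = robust_regression(x, y)
        ols_slope = np.polyfit(x, y, 1)[0]
        assert fit.slope == pytest.approx(ols_slope, abs=0.05)

    def test_outlier_downweighted(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(25)
        y = 2.0 * x + 0.2 * rng.standard_normal(25)
        y[0] += 15.0  # gross outlier
        fit = robust_regression(x, y)
        ols_slope = np.polyfit(x, y, 1)[0]
        assert abs(fit.slope - 2.0) < abs(ols_slope - 2.0)
        assert np.all((fit.weights > 0) | (np.arange(25) == 0))
        assert np.all(fit.weights <= 1.0)
        assert fit.weights.argmin() == 0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            robust_regression([1, 2, 3], [1, 2, 3])


class TestOneSampleT:
    def test_matches_formula_oracle(self):
        vals = np.array([1.2, 1.8, 1.5, 2.1, 1.4])
        t, p = one_sample_t(vals, 1.0)
        se = vals.std(ddof=1) / np.sqrt(5)
        assert t == pytest.approx((vals.mean() - 1.0) / se, rel=1e-12)
        assert 0 < p < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t([2.0, 2.0, 2.0, 2.0], 1.0)
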