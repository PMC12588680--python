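import numpy as np
import pandas as pd
import pytest

from betadyn.semfit import (BehaviorDegenerationModel, CompositeScoreModel,
                            PathModel, adjusted_bonferroni, cumulative_features)


def mediation_data(n=2000, a=0.6, b=0.7, seed=0):
    """X -> M -> Y with standardized true paths a and b."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    m = a * x + np.sqrt(1 - a**2) * rng.standard_normal(n)
    y = b * m + np.sqrt(1 - b**2) * rng.standard_normal(n)
    return pd.DataFrame({"X": x, "M": m, "Y": y})


class TestPathModel:
    def test_from_text_and_cycle_detection(self):
        pm = PathModel.from_text("X -> M\nM -> Y\n# comment\n")
        assert pm.edges == [("X", "M"), ("M", "Y")]
        assert pm.exogenous == ["X"]
        with pytest.raises(ValueError, match="cycle"):
            PathModel([("A", "B"), ("B", "A")])
        with pytest.raises(ValueError, match="parse"):
            PathModel.from_text("X = Y")

    def test_ml_equals_ols_for_recursive_model(self):
        """Closed-form oracle: for a recursive path model with free residuals,
        ML path estimates equal the per-equation OLS coefficients."""
        df = mediation_data()
        fit = PathModel([("X", "M"), ("M", "Y")]).fit(df)
        ols_a = np.polyfit(df["X"], df["M"], 1)[0]
        ols_b = np.polyfit(df["M"], df["Y"], 1)[0]
        assert fit.params["M~X"] == pytest.approx(ols_a, abs=1e-6)
        assert fit.params["Y~M"] == pytest.approx(ols_b, abs=1e-6)

    def test_saturated_model_perfect_fit(self):
        df = mediation_data(n=500, seed=1)
        fit = PathModel([("X", "M"), ("M", "Y"), ("X", "Y")]).fit(df)
        assert fit.df == 0
        assert fit.chi2 < 1e-6
        assert fit.rmsea == 0.0

    def test_rmsea_formula_with_clamp(self):
        df = mediation_data(n=800, seed=2)
        fit = PathModel([("X", "M"), ("M", "Y")]).fit(df)
        expect = np.sqrt(max(fit.chi2 - fit.df, 0.0) / (fit.df * (fit.n - 1)))
        assert fit.rmsea == pytest.approx(expect)
        assert fit.aic == pytest.approx(fit.chi2 + 2 * len(fit.params))

    def test_standardized_coefficients_near_truth(self):
        df = mediation_data(n=5000, a=0.6, b=0.7, seed=3)
        fit = PathModel([("X", "M"), ("M", "Y")]).fit(df)
        assert fit.standardized["M~X"] == pytest.approx(0.6, abs=0.05)
        assert fit.standardized["Y~M"] == pytest.approx(0.7, abs=0.05)
        assert np.isfinite(fit.se).all()

    def test_aic_prefers_generating_model(self):
        """The generating mediation model beats a model with one spurious
        extra path on AIC in most replications."""
        wins = 0
        n_rep = 30
        for s in range(n_rep):
            df = mediation_data(n=500, seed=100 + s)
            aic_true = PathModel([("X", "M"), ("M", "Y")]).fit(df).aic
            aic_extra = PathModel([("X", "M"), ("M", "Y"), ("X", "Y")]).fit(df).aic
            wins += aic_true < aic_extra
        assert wins / n_rep >= 0.7

    def test_insufficient_n_rejected(self):
        df = mediation_data(n=5)
        with pytest.raises(ValueError, match="free parameters"):
            PathModel([("X", "M"), ("M", "Y")]).fit(df)

    def test_singular_covariance_rejected(self):
        df = mediation_data(n=100)
        df["X2"] = df["X"]  # exact collinearity
        with pytest.raises(ValueError, match="positive definite"):
            PathModel([("X", "M"), ("X2", "M")]).fit(df)

    def test_summary_mentions_fit_indices(self):
        fit = PathModel([("X", "M"), ("M", "Y")]).fit(mediation_data(n=300))
        s = fit.summary()
        for token in ("RMSEA", "AIC", "CFI", "SRMR", "M~X"):
            assert token in s


class TestAdjustedBonferroni:
    def test_limits(self):
        assert adjusted_bonferroni([0.01] * 10, 1.0).alpha_adjusted == pytest.approx(0.05)
        assert adjusted_bonferroni([0.01], 0.3).alpha_adjusted == pytest.approx(0.05)
        expect = 1.0 - 0.95 ** (1.0 / 10.0)
        assert adjusted_bonferroni([0.01] * 10, 0.0).alpha_adjusted == pytest.approx(expect)

    def test_monotone_in_correlation(self):
        alphas = [adjusted_bonferroni([0.01] * 8, r).alpha_adjusted
                  for r in (0.0, 0.3, 0.6, 0.9)]
        assert all(a < b for a, b in zip(alphas, alphas[1:]))

    def test_flags_and_validation(self):
        res = adjusted_bonferroni([0.001, 0.04], 0.0)
        assert res.significant == (True, False)
        with pytest.raises(ValueError):
            adjusted_bonferroni([0.01], 1.5)
        with pytest.raises(ValueError):
            adjusted_bonferroni([], 0.5)


class TestCumulativeFeatures:
    @staticmethod
    def _table():
        rows = []
        rng = np.random.default_rng(0)
        for g in ("a", "b"):
            for s in range(3):
                for w in (2, 3, 4, 6, 8):
                    rows.append({"subject": f"{g}{s}", "group": g, "week": w,
                                 "f1": rng.uniform(1, 2), "f2": rng.uniform(5, 6)})
        return pd.DataFrame(rows)

    def test_constant_feature_counts_weeks(self):
        df = self._table()
        df["f1"] = 3.0
        out = cumulative_features(df, ["f1"])
        one = out[out["subject"] == "a0"].sort_values("week")
        assert one["f1"].tolist() == [1.0, 2.0, 3.0, 4.0, 5.0]

    def test_scale_invariance(self):
        df = self._table()
        a = cumulative_features(df, ["f1"])
        df2 = df.copy()
        df2["f1"] *= 2.0
        b = cumulative_features(df2, ["f1"])
        assert np.allclose(a["f1"], b["f1"])

    def test_matches_loop_oracle(self):
        df = self._table()
        out = cumulative_features(df, ["f1", "f2"]).set_index(["subject", "week"])
        for col in ("f1", "f2"):
            for g, sub in df.groupby("group"):
                mean = sub[col].mean()
                for sid, rows in sub.groupby("subject"):
                    rows = rows.sort_values("week")
                    acc = 0.0
                    for _, r in rows.iterrows():
                        acc += r[col] / mean
                        assert out.loc[(sid, r["week"]), col] == pytest.approx(acc)

    def test_incomplete_subject_dropped_and_zero_mean_rejected(self):
        df = self._table()
        df = df.drop(df[(df["subject"] == "a0") & (df["week"] == 4)].index)
        with pytest.warns(UserWarning, match="a0"):
            out = cumulative_features(df, ["f1"])
        assert "a0" not in out["subject"].values
        df2 = self._table()
        df2["f1"] = 0.0
        with pytest.raises(ValueError, match="zero"):
            cumulative_features(df2, ["f1"])


class TestCompositeScore:
    def test_exact_feature_gets_full_weight(self):
        rng = np.random.default_rng(0)
        F = pd.DataFrame({"f1": rng.random(40), "f2": rng.random(40)})
        res = CompositeScoreModel(F, F["f1"]).fit()
        assert res.selected_features == ["f1"]
        assert res.weights["f1"] == pytest.approx(1.0)
        assert res.rmse == pytest.approx(0.0, abs=1e-12)

    def test_weight_recovery(self):
        rng = np.random.default_rng(1)
        F = pd.DataFrame(rng.random((80, 6)), columns=[f"f{i}" for i in range(6)])
        y = 0.7 * F["f0"] + 0.3 * F["f1"] + rng.normal(0, 0.005, 80)
        res = CompositeScoreModel(F, y).fit()
        assert set(res.selected_features) == {"f0", "f1"}
        assert res.weights["f0"] == pytest.approx(0.7, abs=0.05)
        assert res.weights["f1"] == pytest.approx(0.3, abs=0.05)
        assert res.weights.sum() == pytest.approx(1.0)
        assert (res.weights >= 0).all()

    def test_exhaustive_agrees_on_easy_problem(self):
        rng = np.random.default_rng(2)
        F = pd.DataFrame(rng.random((60, 4)), columns=list("abcd"))
        y = 0.5 * F["a"] + 0.5 * F["c"]
        res = CompositeScoreModel(F, y).fit(method="exhaustive")
        assert set(res.selected_features) >= {"a", "c"}
        assert res.rmse == pytest.approx(0.0, abs=1e-10)

    def test_noise_candidates_do_not_beat_baseline(self):
        rng = np.random.default_rng(3)
        F = pd.DataFrame(rng.random((60, 5)), columns=list("abcde"))
        y = rng.random(60)
        res = CompositeScoreModel(F, y).fit()
        assert res.rmse >= res.baseline_rmse - 0.05

    def test_all_constant_rejected(self):
        F = pd.DataFrame({"f1": np.ones(10)})
        with pytest.raises(ValueError, match="constant"):
            CompositeScoreModel(F, np.arange(10.0))


class TestBehaviorDegenerationCurve:
    def test_step_data_midpoint(self):
        x = np.arange(0.0, 101.0, 2.0)
        beh = np.where(x > 50.0, 5.0, 0.0)
        c = BehaviorDegenerationModel(x, beh).fit()["all"]
        assert 45.0 <= c.midpoint <= 55.0
        assert c.slope < 0
        # predicted probability falls across the midpoint
        p = c.predict(np.array([10.0, 90.0]))
        assert p[0] > 0.9 > 0.1 > p[1]

    def test_null_slope_ci_covers_zero(self):
        rng = np.random.default_rng(0)
        m = BehaviorDegenerationModel(rng.uniform(0, 100, 60), rng.normal(0, 1, 60))
        lo, hi = m.bootstrap_slope_ci("all", n_boot=200, seed=1)
        assert lo <= 0.0 <= hi

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single"):
            BehaviorDegenerationModel(np.arange(10.0), np.ones(10)).fit()

    def test_per_group_fits(self):
        x = np.tile(np.arange(0.0, 100.0, 5.0), 2)
        beh = np.where(x > 40.0, 4.0, 0.0)
        groups = np.repeat(["g1", "g2"], 20)
        curves = BehaviorDegenerationModel(x, beh, groups).fit()
        assert set(curves) == {"g1", "g2"}
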