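import warnings

import numpy as np
import pandas as pd
import pytest

from craniosemg.cohort_stats import (
    adjust_confounders,
    cart_impute,
    chi2_2x2_yates,
    clean_outliers,
    cronbach_alpha,
    fit_factor_model,
    group_effect,
    integrated_outcome,
    mediation_paths,
    parallel_analysis,
    welch_t_from_summary,
)


class TestCleanOutliers:
    def test_flagging_a_gross_outlier(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0, 100.0]})
        out, flags = clean_outliers(df)
        assert flags["a"].sum() == 1
        assert np.isnan(out["a"].iloc[-1])

    def test_constant_column_untouched(self):
        df = pd.DataFrame({"a": [2.0] * 10})
        out, flags = clean_outliers(df)
        assert flags["a"].sum() == 0

    def test_boundary_values_kept(self):
        x = pd.Series(np.arange(9, dtype=float))
        q1, q3 = x.quantile(0.25), x.quantile(0.75)
        hi = q3 + 1.5 * (q3 - q1)
        df = pd.DataFrame({"a": list(x) + [hi]})
        _, flags = clean_outliers(df)
        assert flags["a"].sum() == 0

    def test_gaussian_flag_rate_matches_tukey_rule(self):
        x = np.random.default_rng(0).standard_normal(10_000)
        _, flags = clean_outliers(pd.DataFrame({"a": x}))
        rate = flags["a"].mean() * 100
        assert rate == pytest.approx(0.7, abs=0.4)

    def test_shape_preserved(self):
        df = pd.DataFrame(np.random.default_rng(1).standard_normal((30, 4)))
        df.columns = list("abcd")
        out, _ = clean_outliers(df)
        assert out.shape == df.shape


class TestCartImpute:
    def test_no_missing_is_identity(self):
        df = pd.DataFrame(np.random.default_rng(0).standard_normal((30, 3)), columns=list("abc"))
        pd.testing.assert_frame_equal(cart_impute(df), df)

    def test_deterministic_relation_recovered(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 10, 200)
        df = pd.DataFrame({"x": x, "y": 2 * x})
        df.loc[10, "y"] = np.nan
        out = cart_impute(df, seed=0)
        assert out.loc[10, "y"] == pytest.approx(2 * df.loc[10, "x"], rel=0.1)

    def test_same_seed_identical(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.standard_normal((50, 4)), columns=list("abcd"))
        df.iloc[::7, 1] = np.nan
        pd.testing.assert_frame_equal(cart_impute(df, seed=3), cart_impute(df, seed=3))

    def test_fully_missing_column_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="b"):
            cart_impute(df)

    def test_row_column_counts_unchanged(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.standard_normal((40, 5)), columns=list("abcde"))
        df.iloc[::5, 2] = np.nan
        cleaned, _ = clean_outliers(df)
        out = cart_impute(cleaned, seed=0)
        assert out.shape == df.shape
        assert not out.isna().any().any()


class TestGroupEffect:
    def _cohort(self, seed, shift=0.0, tau2=0.05):
        rng = np.random.default_rng(seed)
        subj = np.repeat(np.arange(26), 4)
        grp = np.repeat(np.array([1] * 16 + [0] * 10), 4)
        y = (
            np.sqrt(tau2) * np.repeat(rng.standard_normal(26), 4)
            + np.sqrt(1 - tau2) * rng.standard_normal(104)
            + shift * grp
        )
        return y, grp, subj

    def test_null_effect_small(self):
        hits = 0
        for seed in range(30):
            y, g, s = self._cohort(seed)
            hits += abs(group_effect(y, g, s).cohens_d) < 0.5
        assert hits >= 27  # >= 90%

    def test_injected_shift_recovered(self):
        hits = 0
        for seed in range(30):
            y, g, s = self._cohort(seed, shift=1.0)
            hits += 0.6 <= group_effect(y, g, s).cohens_d <= 1.4
        assert hits >= 27

    def test_matches_two_sample_d_without_subject_variance(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(104) + 0.8 * np.repeat([1] * 16 + [0] * 10, 4)
        g = np.repeat([1] * 16 + [0] * 10, 4)
        subj = np.arange(104)  # one recording per "subject": no clustering
        eff = group_effect(y, g, subj)
        a, h = y[g == 1], y[g == 0]
        sp = np.sqrt(
            ((len(a) - 1) * a.var(ddof=1) + (len(h) - 1) * h.var(ddof=1))
            / (len(a) + len(h) - 2)
        )
        assert eff.cohens_d == pytest.approx((a.mean() - h.mean()) / sp, abs=0.05)


class TestSummaryTests:
    def test_welch_t_identical_groups(self):
        t, df, p = welch_t_from_summary(5, 1, 10, 5, 1, 10)
        assert t == 0.0

    def test_welch_t_speaking_rate_row(self):
        t, _, p = welch_t_from_summary(132.86, 42.37, 16, 183.65, 23.02, 10)
        assert round(t, 2) == -3.95
        assert p < 0.001

    def test_welch_t_age_row(self):
        t, _, _ = welch_t_from_summary(58.75, 14.58, 16, 66.80, 13.02, 10)
        assert round(t, 2) == -1.46

    def test_welch_t_zero_variances_rejected(self):
        with pytest.raises(ValueError):
            welch_t_from_summary(1, 0, 10, 2, 0, 10)

    def test_chi2_equal_proportions_zero(self):
        chi2, _ = chi2_2x2_yates(5, 5, 5, 5)
        assert chi2 == 0.0

    def test_chi2_sex_row(self):
        chi2, p = chi2_2x2_yates(6, 10, 7, 3)
        assert round(chi2, 2) == 1.46

    def test_chi2_hand_formula(self):
        a, b, c, d = 1, 9, 9, 1
        n = 20
        expect = n * (abs(a * d - b * c) - n / 2) ** 2 / (10 * 10 * 10 * 10)
        chi2, _ = chi2_2x2_yates(a, b, c, d)
        assert chi2 == pytest.approx(expect)

    def test_chi2_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi2_2x2_yates(0, 0, 3, 4)


class TestParallelAnalysis:
    def test_gaussian_noise_keeps_at_most_one(self):
        hits = 0
        for seed in range(10):
            X = np.random.default_rng(seed).standard_normal((104, 60))
            hits += parallel_analysis(X, n_sims=50, seed=seed) <= 1
        assert hits >= 9

    def test_three_strong_factors_detected(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            F = rng.standard_normal((104, 3))
            L = np.zeros((30, 3))
            for j in range(3):
                L[j * 10 : (j + 1) * 10, j] = 0.85
            X = F @ L.T + 0.4 * rng.standard_normal((104, 30))
            hits += parallel_analysis(X, n_sims=50, seed=seed) == 3
        assert hits >= 9

    def test_deterministic_given_seed(self):
        X = np.random.default_rng(0).standard_normal((104, 60))
        assert parallel_analysis(X, seed=5) == parallel_analysis(X, seed=5)

    def test_constant_column_named(self):
        X = np.random.default_rng(0).standard_normal((104, 5))
        X[:, 3] = 1.0
        with pytest.raises(ValueError, match="3"):
            parallel_analysis(X)


class TestFactorModel:
    def test_single_factor_collects_all_features(self):
        rng = np.random.default_rng(0)
        f = rng.standard_normal(200)
        X = pd.DataFrame(
            0.8 * f[:, None] + 0.6 * rng.standard_normal((200, 12)),
            columns=[f"v{i}" for i in range(12)],
        )
        model = fit_factor_model(X, 1)
        assert len(model.component_map["F1"]) == 12

    def test_scores_preserve_factor_correlations(self, feature_cohort):
        table, _ = feature_cohort
        from craniosemg.network import FEATURE_NAMES

        model = fit_factor_model(table[FEATURE_NAMES], 10)
        score_corr = np.corrcoef(model.scores.to_numpy(), rowvar=False)
        assert np.abs(score_corr - model.phi).max() <= 0.05

    def test_scale_invariance_of_scores(self):
        rng = np.random.default_rng(1)
        f = rng.standard_normal(150)
        X = pd.DataFrame(
            0.8 * f[:, None] + 0.6 * rng.standard_normal((150, 8)),
            columns=[f"v{i}" for i in range(8)],
        )
        m1 = fit_factor_model(X, 1)
        m2 = fit_factor_model(X * np.array([1e3, 1, 10, 1, 1, 1, 0.01, 1]), 1)
        np.testing.assert_allclose(
            m1.scores.to_numpy(), m2.scores.to_numpy(), atol=1e-8
        )

    def test_incomplete_matrix_rejected(self):
        X = pd.DataFrame(np.random.default_rng(2).standard_normal((30, 4)))
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            fit_factor_model(X, 1)


class TestCronbachAlpha:
    def test_duplicated_item_is_one(self):
        x = np.random.default_rng(0).standard_normal(100)
        assert cronbach_alpha(np.column_stack([x, x])) == pytest.approx(1.0)

    def test_spearman_brown_two_items(self):
        rng = np.random.default_rng(1)
        n = 200_000
        a = rng.standard_normal(n)
        b = 0.5 * a + np.sqrt(1 - 0.25) * rng.standard_normal(n)
        assert cronbach_alpha(np.column_stack([a, b])) == pytest.approx(2 / 3, abs=0.01)

    def test_independent_items_near_zero(self):
        X = np.random.default_rng(2).standard_normal((10_000, 5))
        assert abs(cronbach_alpha(X)) < 0.05

    def test_single_item_rejected(self):
        with pytest.raises(ValueError):
            cronbach_alpha(np.ones((10, 1)))


class TestIntegratedOutcome:
    def _table(self):
        rng = np.random.default_rng(0)
        return pd.DataFrame(
            {
                "group": ["HC"] * 10 + ["ALS+B"] * 10,
                "Bulb_ALSFRS": np.concatenate([np.full(10, np.nan), rng.integers(4, 12, 10)]),
                "Intell": np.concatenate([rng.uniform(97, 100, 10), rng.uniform(60, 95, 10)]),
                "SR": rng.uniform(100, 200, 20),
            }
        )

    def test_first_weight_only_returns_z_bulbar(self):
        tab = self._table()
        out = integrated_outcome(tab, weights=(1, 0, 0))
        bulb = tab["Bulb_ALSFRS"].copy()
        bulb[tab["group"] == "HC"] = 12.0
        z = (bulb - bulb.mean()) / bulb.std(ddof=1)
        np.testing.assert_allclose(out, z)

    def test_cohort_max_intelligibility_maps_to_zero_log_term(self):
        tab = self._table()
        imax = tab["Intell"].idxmax()
        log_term = np.log10(tab["Intell"].max() + 1 - tab["Intell"])
        assert log_term[imax] == pytest.approx(0.0)

    def test_zero_weights_give_zero_outcome(self):
        out = integrated_outcome(self._table(), weights=(0, 0, 0))
        np.testing.assert_array_equal(out, 0.0)

    def test_invalid_intelligibility_rejected(self):
        tab = self._table()
        tab.loc[0, "Intell"] = 105.0
        with pytest.raises(ValueError, match="Intell"):
            integrated_outcome(tab)


class TestMediation:
    def _paths(self, a, b, n=200, seed=0, n_boot=300):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal(n)
        M = a * X + 0.5 * rng.standard_normal(n)
        Y = 0.2 * X + b * M + 0.5 * rng.standard_normal(n)
        return mediation_paths(
            pd.DataFrame({"c": X}),
            pd.Series(M),
            pd.Series(Y),
            pd.Series(np.arange(n)),
            n_boot=n_boot,
            seed=seed,
        )[0]

    def test_zero_b_path_ci_contains_zero(self):
        res = self._paths(a=0.5, b=0.0)
        lo, hi = res.indirect_ci
        assert lo <= 0.0 <= hi

    def test_recovery_of_planted_indirect_effect(self):
        res = self._paths(a=0.5, b=0.5)
        assert 0.15 <= res.indirect <= 0.35
        assert res.indirect == pytest.approx(res.a_path * res.b_path)

    def test_ci_bounds_ordered_and_deterministic(self):
        r1 = self._paths(a=0.3, b=0.4, seed=5)
        r2 = self._paths(a=0.3, b=0.4, seed=5)
        assert r1.indirect_ci[0] <= r1.indirect_ci[1]
        assert r1.indirect_ci == r2.indirect_ci

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="subject"):
            mediation_paths(
                pd.DataFrame({"c": np.arange(8.0)}),
                pd.Series(np.arange(8.0)),
                pd.Series(np.arange(8.0)),
                pd.Series(np.arange(8)),
            )


class TestAdjustConfounders:
    def _covs(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "age": rng.uniform(40, 80, n),
                "sex": rng.choice(["F", "M"], n),
                "cognitive_status": rng.integers(0, 2, n),
            }
        )

    def test_orthogonal_covariates_leave_centered_composite(self):
        rng = np.random.default_rng(1)
        comp = pd.DataFrame({"c": rng.standard_normal(500)})
        adj = adjust_confounders(comp, self._covs(500, 1))
        r = np.corrcoef(adj["c"], comp["c"] - comp["c"].mean())[0, 1]
        assert r > 0.99

    def test_exact_linear_dependence_removed(self):
        covs = self._covs(200, 2)
        comp = pd.DataFrame({"c": 2.0 * covs["age"].to_numpy()})
        adj = adjust_confounders(comp, covs)
        assert np.abs(adj["c"]).max() < 1e-6

    def test_planted_age_effect_removed(self):
        rng = np.random.default_rng(3)
        covs = self._covs(400, 3)
        comp = pd.DataFrame({"c": covs["age"] * 1.0 + rng.standard_normal(400)})
        adj = adjust_confounders(comp, covs)
        assert abs(np.corrcoef(adj["c"], covs["age"])[0, 1]) < 0.05

    def test_collinear_covariate_dropped_with_warning(self):
        covs = self._covs(100, 4)
        covs["age2"] = covs["age"] * 2.0
        comp = pd.DataFrame({"c": np.random.default_rng(4).standard_normal(100)})
        with pytest.warns(UserWarning, match="collinear"):
            adjust_confounders(comp, covs)

    def test_fit_on_training_rows_only(self):
        rng = np.random.default_rng(5)
        covs = self._covs(100, 5)
        comp = pd.DataFrame({"c": rng.standard_normal(100)})
        adj = adjust_confounders(comp, covs, fit_rows=np.arange(80))
        # residuals on the training block are orthogonal to covariates there
        age_tr = covs["age"].to_numpy()[:80]
        assert abs(np.corrcoef(adj["c"][:80], age_tr)[0, 1]) < 1e-6
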