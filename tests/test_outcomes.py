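import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from jipclust.outcomes import (chi2_crosstab, cox_fit, cox_lrt, km_estimate,
                               kruskal_dunn, locf_remission, logrank_test,
                               merge_sparse_levels, ordinal_fit,
                               schoenfeld_ph_test)


class TestKaplanMeier:
    def test_no_events_gives_constant_one(self):
        km = km_estimate([5, 8, 12], [0, 0, 0])
        assert np.allclose(km.survival, 1.0)

    def test_hand_product_limit(self):
        km = km_estimate([1, 2, 3, 4], [1, 0, 1, 0])
        assert km.at(1) == pytest.approx(0.75)
        assert km.at(3) == pytest.approx(0.375)

    def test_all_events_at_one_time(self):
        km = km_estimate([1, 1, 1], [1, 1, 1])
        assert km.at(1) == pytest.approx(0.0)

    def test_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, 50)
        km = km_estimate(t, np.ones(50, dtype=int))
        for q in [2.0, 5.0, 12.0]:
            assert km.at(q) == pytest.approx((t > q).mean())

    def test_greenwood_se_positive_between_events(self):
        km = km_estimate([1, 2, 3, 4, 5], [1, 1, 0, 1, 0])
        inner = (km.survival > 0) & (km.survival < 1)
        assert (km.se[inner] > 0).all()

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([0, 1], [1, 1])


class TestLogrank:
    def test_identical_groups_give_zero(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 1, 0, 1, 1, 1, 0, 1]
        g = [0] * 4 + [1] * 4
        stat, df, p = logrank_test(t, e, g)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df == 1

    def test_group_permutation_invariance(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(5, 30)
        e = rng.integers(0, 2, 30)
        e[0] = 1
        g = rng.integers(0, 2, 30)
        s1, _, _ = logrank_test(t, e, g)
        s2, _, _ = logrank_test(t, e, 1 - g)
        assert s1 == pytest.approx(s2)

    def test_matches_hand_tabulated_toy(self):
        # groups A: events at 1, 3; B: event at 2, censored at 4
        t = np.array([1.0, 3.0, 2.0, 4.0])
        e = np.array([1, 1, 1, 0])
        g = np.array([0, 0, 1, 1])
        # hand computation over event times 1,2,3:
        # t=1: nA=2,nB=2,d=1 -> eA=1/2, v=1/4... aggregated below
        O_A = 2.0
        E_A = 2 / 4 + 1 / 3 + 1 / 2
        V = (1 * (2 * 2) / (4 * 4)) + (1 * (1 * 2) / (3 * 3)) \
            + (1 * (1 * 1) / (2 * 2))
        expect = (O_A - E_A) ** 2 / V
        stat, _, _ = logrank_test(t, e, g)
        assert stat == pytest.approx(expect, rel=1e-6)

    def test_matches_squared_cox_score_on_tiefree_data(self):
        # two-group log-rank == score test of Cox at beta=0 (no ties)
        rng = np.random.default_rng(2)
        t = rng.exponential(5, 40) + rng.random(40) * 1e-6
        e = np.ones(40, dtype=int)
        x = rng.integers(0, 2, 40).astype(float)
        order = np.argsort(-t)
        U = 0.0
        I = 0.0
        for i in np.argsort(t):
            risk = t >= t[i]
            if e[i]:
                xbar = x[risk].mean()
                U += x[i] - xbar
                I += ((x[risk] - xbar) ** 2).mean()
        score_sq = U ** 2 / I
        stat, _, _ = logrank_test(t, e, x.astype(int))
        assert stat == pytest.approx(score_sq, abs=1e-6)

    def test_requires_events_and_groups(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [0, 0], [0, 1])
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], [0, 0])


def _surv_frame(t, e, x):
    return pd.DataFrame({"time": t, "event": e, "group": x})


class TestCox:
    def test_identical_groups_give_null_effect(self):
        t = [1, 2, 3, 4, 5, 1, 2, 3, 4, 5]
        e = [1] * 10
        x = [0] * 5 + [1] * 5
        fit = cox_fit(_surv_frame(t, e, x), ["group"])
        # same event times in both arms: HR estimable at ~1
        assert fit.hazard_ratios["group"] == pytest.approx(1.0, abs=0.05)

    def test_matches_partial_likelihood_grid_search(self):
        # tie-free 8-patient data: beta-hat from lifelines must equal the
        # brute-force maximizer of the exact partial likelihood
        t = np.array([1.0, 2.0, 3.5, 4.0, 5.5, 6.0, 7.5, 9.0])
        e = np.array([1, 1, 0, 1, 1, 0, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 1.0, 0.0, 0.0, 1.0, 0.0])

        def neg_pll(beta):
            ll = 0.0
            for i in range(len(t)):
                if e[i]:
                    risk = t >= t[i]
                    ll += beta * x[i] - np.log(
                        np.exp(beta * x[risk]).sum())
            return -ll

        oracle = minimize_scalar(neg_pll, bounds=(-4, 4),
                                 method="bounded",
                                 options={"xatol": 1e-10}).x
        fit = cox_fit(_surv_frame(t, e, x), ["group"])
        assert fit.coefficients["group"] == pytest.approx(oracle, abs=1e-4)

    def test_efron_and_breslow_agree_on_tiefree_data(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(5, 60)
        e = rng.integers(0, 2, 60)
        e[:5] = 1
        x = rng.normal(size=60)
        d = _surv_frame(t, e, x)
        f1 = cox_fit(d, ["group"], ties="efron")
        f2 = cox_fit(d, ["group"], ties="breslow")
        assert f1.coefficients["group"] == pytest.approx(
            f2.coefficients["group"], abs=1e-5)

    def test_ci_brackets_hr_and_loglik_beats_null(self):
        rng = np.random.default_rng(4)
        n = 200
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(np.where(x > 0, 5, 10))
        d = _surv_frame(t, np.ones(n, dtype=int), x)
        fit = cox_fit(d, ["group"])
        assert fit.ci_lower["group"] < fit.hazard_ratios["group"] \
            < fit.ci_upper["group"]
        assert fit.log_likelihood >= fit.null_log_likelihood

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            cox_fit(_surv_frame([1, 2], [0, 0], [0, 1]), ["group"])


class TestCoxLRT:
    def _fits(self, seed=5, n=150, noise=True):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 2, n).astype(float)
        z = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.8 * x))
        d = pd.DataFrame({"time": t, "event": np.ones(n, dtype=int),
                          "group": x, "noise": z})
        nested = cox_fit(d, ["group"])
        full = cox_fit(d, ["group", "noise"])
        return nested, full

    def test_identical_models_give_zero(self):
        nested, _ = self._fits()
        stat, df, p = cox_lrt(nested, nested)
        assert (stat, df, p) == (0.0, 0, 1.0)

    def test_pure_noise_covariate_is_insignificant(self):
        pvals = []
        for seed in range(15):
            nested, full = self._fits(seed=seed)
            stat, df, p = cox_lrt(nested, full)
            assert df == 1
            pvals.append(p)
        # under the null, p-values are roughly uniform
        assert np.mean(np.array(pvals) < 0.05) <= 0.2
        assert np.mean(pvals) == pytest.approx(0.5, abs=0.25)

    def test_informative_clusters_add_signal(self):
        # cluster labels carrying hazard structure beyond a covariate
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n = 400
            cl = rng.integers(0, 2, n).astype(float)
            age = rng.normal(size=n)
            t = rng.exponential(np.exp(-0.7 * cl + 0.2 * age))
            d = pd.DataFrame({"time": t, "event": np.ones(n, dtype=int),
                              "age": age, "cluster": cl})
            nested = cox_fit(d, ["age"])
            full = cox_fit(d, ["age", "cluster"])
            if cox_lrt(nested, full)[2] < 0.05:
                hits += 1
        assert hits >= 18

    def test_non_nested_rejected(self):
        nested, full = self._fits()
        with pytest.raises(ValueError):
            cox_lrt(full, nested)


class TestSchoenfeld:
    def test_residual_is_covariate_minus_riskset_mean(self):
        # at beta-hat, each Schoenfeld residual equals the covariate minus
        # the risk-set weighted mean; check on 5 patients directly
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        e = np.array([1, 1, 1, 0, 1])
        x = np.array([0.0, 1.0, 0.0, 1.0, 1.0])
        d = _surv_frame(t, e, x)
        fit = cox_fit(d, ["group"])
        beta = fit.coefficients["group"]
        resid = fit._fitter.compute_residuals(d, "schoenfeld")
        # residuals are indexed by the original row position of each event
        for row_idx, day in [(0, 1.0), (1, 2.0), (2, 3.0)]:
            risk = t >= day
            w = np.exp(beta * x[risk])
            expected = x[row_idx] - (w * x[risk]).sum() / w.sum()
            val = float(resid.loc[row_idx].iloc[0])
            assert val == pytest.approx(expected, abs=1e-6)

    def test_type_one_error_near_nominal_under_ph(self):
        rejections = 0
        reps = 150
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            n = 120
            x = rng.normal(size=n)
            t = rng.exponential(np.exp(-0.5 * x))
            c = rng.exponential(2.0, n)
            obs = np.minimum(t, c)
            e = (t <= c).astype(int)
            d = _surv_frame(obs, e, x)
            fit = cox_fit(d, ["group"])
            p = schoenfeld_ph_test(fit)["p"].iloc[0]
            rejections += p < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.05)

    def test_detects_time_varying_effect(self):
        rejections = 0
        reps = 25
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            n = 300
            x = rng.integers(0, 2, n).astype(float)
            # group 1 has a sharply decreasing hazard (Weibull shape 0.4)
            # against a constant-hazard group 0 -> strong PH violation
            t = np.where(x > 0, rng.weibull(0.4, n),
                         rng.exponential(1.0, n))
            t = np.maximum(t, 1e-4)
            d = _surv_frame(t, np.ones(n, dtype=int), x)
            fit = cox_fit(d, ["group"])
            p = schoenfeld_ph_test(fit)["p"].iloc[0]
            rejections += p < 0.05
        assert rejections / reps > 0.6

    def test_needs_three_events(self):
        d = _surv_frame([1, 2, 3], [1, 1, 0], [0, 1, 0])
        fit = cox_fit(d, ["group"])
        with pytest.raises(ValueError):
            schoenfeld_ph_test(fit)


class TestLocfRemission:
    def test_remission_reached_at_later_visit(self):
        flag, first = locf_remission([(120, 2.0), (240, 1.4)], 365)
        assert flag is True and first == 240

    def test_single_value_above_cut(self):
        flag, first = locf_remission([(120, 1.7)], 365)
        assert flag is False and first is None

    def test_flare_after_early_remission(self):
        flag, first = locf_remission([(120, 1.4), (300, 2.1)], 365)
        assert flag is False
        assert first == 120

    def test_empty_series_is_missing_marker(self):
        assert locf_remission([], 365) == (None, None)

    def test_never_true_without_value_below_cut(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            days = np.sort(rng.choice(400, 5, replace=False))
            vals = rng.uniform(1.6, 6.0, 5)
            flag, first = locf_remission(list(zip(days, vals)), 365)
            assert flag in (False, None) and first is None


class TestChi2:
    def test_homogeneous_table(self):
        stat, df, p = chi2_crosstab([[10, 10], [10, 10]])
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_hand_computed_value(self):
        stat, df, p = chi2_crosstab([[20, 10], [10, 20]])
        assert stat == pytest.approx(100 / 15)
        assert df == 1

    def test_transpose_invariance(self):
        t = np.array([[5, 9, 2], [7, 3, 11]])
        assert chi2_crosstab(t)[0] == pytest.approx(chi2_crosstab(t.T)[0])

    def test_degenerate_margins_rejected(self):
        with pytest.raises(ValueError):
            chi2_crosstab([[0, 0], [1, 2]])


class TestKruskalDunn:
    def test_hand_computed_h(self):
        H, p, pairs = kruskal_dunn({"a": [1, 2], "b": [3, 4]})
        assert H == pytest.approx(2.4)

    def test_identical_distributions_give_small_h(self):
        x = list(range(20))
        H, p, _ = kruskal_dunn({"a": x, "b": x})
        assert H < 0.2 and p > 0.5

    def test_shifted_group_has_smallest_dunn_pvalues(self):
        rng = np.random.default_rng(0)
        groups = {"a": rng.normal(0, 1, 40), "b": rng.normal(0, 1, 40),
                  "c": rng.normal(2.5, 1, 40)}
        H, p, pairs = kruskal_dunn(groups)
        with_c = pairs[(pairs.group1 == "c") | (pairs.group2 == "c")]
        without_c = pairs[(pairs.group1 != "c") & (pairs.group2 != "c")]
        assert with_c["p"].max() < without_c["p"].min()

    def test_holm_adjustment_monotone(self):
        rng = np.random.default_rng(1)
        groups = {g: rng.normal(i, 1, 25) for i, g in enumerate("abcd")}
        _, _, pairs = kruskal_dunn(groups, adjust="holm")
        assert (pairs["p_adj"] >= pairs["p"] - 1e-12).all()
        assert (pairs["p_adj"] <= 1.0).all()

    def test_all_identical_values(self):
        H, p, pairs = kruskal_dunn({"a": [1, 1], "b": [1, 1]})
        assert H == 0.0 and p == 1.0


class TestOrdinal:
    def test_null_model_recovers_marginal_thresholds(self):
        rng = np.random.default_rng(0)
        n = 4000
        y = rng.choice([1, 2, 3], size=n, p=[0.5, 0.3, 0.2])
        groups = rng.integers(0, 2, n)
        fit = ordinal_fit(y, groups)
        assert abs(fit.coefficients.iloc[0]) < 0.15
        assert fit.thresholds[0] == pytest.approx(0.0, abs=0.15)
        assert fit.thresholds[1] == pytest.approx(np.log(0.8 / 0.2),
                                                  abs=0.15)

    def test_thresholds_strictly_increasing(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 4, 500)
        g = rng.integers(0, 3, 500)
        fit = ordinal_fit(merge_sparse_levels(y)[0], g)
        assert (np.diff(fit.thresholds) > 0).all()

    def test_recovers_planted_shift_within_two_se(self):
        rng = np.random.default_rng(2)
        n = 2000
        g = rng.integers(0, 2, n)
        eta = 1.0 * g
        th = np.array([-1.0, 0.5, 1.5])
        u = rng.random(n)
        cum = 1 / (1 + np.exp(-(th[None, :] - eta[:, None])))
        y = (u[:, None] >= cum).sum(axis=1)
        fit = ordinal_fit(y, g, reference=0)
        beta = fit.coefficients["cluster[1]"]
        se = fit.standard_errors["cluster[1]"]
        assert abs(beta - 1.0) < 2 * se

    def test_predicted_category_probabilities_sum_to_one(self):
        rng = np.random.default_rng(3)
        y = rng.integers(1, 4, 300)
        g = rng.integers(0, 2, 300)
        fit = ordinal_fit(y, g)
        probs = fit._result.predict()
        np.testing.assert_allclose(np.asarray(probs).sum(axis=1), 1.0,
                                   atol=1e-8)

    def test_single_category_rejected(self):
        with pytest.raises(ValueError):
            ordinal_fit(np.ones(50, dtype=int),
                        np.random.default_rng(0).integers(0, 2, 50))


class TestDasCategories:
    def test_band_mapping(self):
        from jipclust.outcomes import das_categories
        out = das_categories([1.0, 2.39, 2.4, 3.69, 3.7, 6.0])
        assert out.tolist() == [0, 0, 1, 1, 2, 2]

    def test_ordinal_fit_with_activity_covariate(self):
        from jipclust.outcomes import das_categories
        rng = np.random.default_rng(9)
        n = 1500
        g = rng.integers(0, 2, n)
        das = rng.uniform(1.5, 5.5, n)
        cat = das_categories(das)
        eta = 0.8 * g + 0.5 * cat
        th = np.array([-0.5, 1.0, 2.5])
        cum = 1 / (1 + np.exp(-(th[None, :] - eta[:, None])))
        y = (rng.random(n)[:, None] >= cum).sum(axis=1)
        fit = ordinal_fit(y, g, covariate=pd.Series(cat), reference=0)
        assert (np.diff(fit.thresholds) > 0).all()
        b = fit.coefficients
        assert abs(b["cluster[1]"] - 0.8) < \
            3 * fit.standard_errors["cluster[1]"]
        assert b["covariate"] > 0


class TestMergeSparseLevels:
    def test_zero_merged_into_one(self):
        merged, mapping = merge_sparse_levels([0, 1, 2, 3])
        assert merged.tolist() == [1, 1, 2, 3]
        assert mapping[0] == 1

    def test_no_zeros_unchanged(self):
        merged, _ = merge_sparse_levels([1, 2, 3, 2])
        assert merged.tolist() == [1, 2, 3, 2]

    def test_all_zero_collapse_warns(self):
        with pytest.warns(UserWarning):
            merged, _ = merge_sparse_levels([0, 0, 0])
        assert merged.tolist() == [1, 1, 1]
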