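"""Inference chain: Spearman, proportional-odds, OLS, restriction, transforms."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.optimize import minimize
from scipy.special import expit

from iacdens.cohort import COVARIATE_ORDER, simulate_cohort
from iacdens.stats import (
    describe_cohort,
    fit_linear_standardized,
    fit_proportional_odds,
    ln_transform,
    restrict_sensitivity,
    spearman_with_ci,
)


class TestSpearman:
    def test_perfect_monotone(self, rng):
        x = np.sort(rng.normal(size=30))
        res = spearman_with_ci(x, np.exp(x), n_boot=50, seed=1)
        assert res.spearman_rho == pytest.approx(1.0)
        res = spearman_with_ci(x, -np.exp(x), n_boot=50, seed=1)
        assert res.spearman_rho == pytest.approx(-1.0)

    def test_ties_match_rank_enumeration_oracle(self, rng):
        x = rng.integers(0, 5, size=20).astype(float)  # heavy ties
        y = rng.integers(0, 5, size=20).astype(float)
        res = spearman_with_ci(x, y, n_boot=10, seed=2)
        # oracle: explicit mid-rank assignment + Pearson-on-ranks formula
        def midranks(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2.0
                i = j
            return ranks
        rx, ry = midranks(x), midranks(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert res.spearman_rho == pytest.approx(expected, abs=1e-12)
        assert res.spearman_rho == pytest.approx(sps.spearmanr(x, y).statistic, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        r1 = spearman_with_ci(x, y, n_boot=10, seed=3).spearman_rho
        r2 = spearman_with_ci(np.exp(x), y**3, n_boot=10, seed=3).spearman_rho
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_ci_brackets_estimate(self, rng):
        x = rng.normal(size=200)
        y = 0.7 * x + rng.normal(size=200)
        res = spearman_with_ci(x, y, n_boot=500, seed=4)
        assert -1 <= res.ci_low <= res.spearman_rho <= res.ci_high <= 1

    def test_constant_margin_flagged(self):
        res = spearman_with_ci(np.ones(20), np.arange(20.0), n_boot=10, seed=5)
        assert res.degenerate and np.isnan(res.spearman_rho)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            spearman_with_ci(np.arange(5.0), np.arange(5.0))


class TestProportionalOdds:
    def test_two_by_two_closed_form(self):
        x = np.array([1.0] * 30 + [0.0] * 70).reshape(-1, 1)
        y = np.array([2] * 10 + [1] * 20 + [2] * 30 + [1] * 40)
        fit = fit_proportional_odds(x, y)
        assert fit.odds_ratios[0] == pytest.approx((10 * 40) / (20 * 30), abs=1e-6)
        assert fit.converged

    def test_k2_equals_binary_logistic_regression(self, rng):
        n = 400
        X = pd.DataFrame({"a": rng.normal(size=n), "b": (rng.random(n) < 0.4) * 1.0})
        eta = 0.8 * X["a"] - 0.5 * X["b"]
        y = (rng.random(n) < expit(eta)).astype(int) + 1
        fit = fit_proportional_odds(X, y)
        # shared-oracle: statsmodels Logit on the same data
        import statsmodels.api as sm

        ref = sm.Logit(y - 1, sm.add_constant(X)).fit(disp=False)
        assert np.allclose(fit.coef, ref.params[["a", "b"]].to_numpy(), atol=1e-6)

    def test_intercept_only_reproduces_observed_frequencies(self, rng):
        y = rng.integers(1, 5, size=600)
        fit = fit_proportional_odds(np.empty((600, 0)), y)
        cum_fit = expit(fit.cutpoints)
        cum_obs = np.array([(y <= k).mean() for k in (1, 2, 3)])
        assert np.allclose(cum_fit, cum_obs, atol=1e-8)

    def test_loglik_matches_generic_optimizer(self):
        """Our Newton optimum is at least as good as a derivative-free
        maximizer started from zeros, to 1e-4 in log-likelihood."""
        df = simulate_cohort(n=500, seed=21)
        cols = ["hypertension", "female", "non_hdl"]
        X = df[cols].to_numpy(float)
        y = df["density_category"].to_numpy()
        fit = fit_proportional_odds(df[cols], y)

        K = 7

        def nll(params):  # independent likelihood implementation
            alpha = np.concatenate([[params[0]], params[0] + np.cumsum(np.exp(params[1 : K - 1]))])
            beta = params[K - 1 :]
            eta = X @ beta
            a = np.concatenate([[-np.inf], alpha, [np.inf]])
            p = expit(a[y] - eta) - expit(a[y - 1] - eta)
            if np.any(p <= 0):
                return 1e10
            return -np.log(p).sum()

        x0 = np.zeros(K - 1 + len(cols))
        res = minimize(nll, x0, method="Powell", options={"maxiter": 20000, "xtol": 1e-10})
        assert fit.loglik >= -res.fun - 1e-4

    def test_loglik_non_decreasing_across_iterations(self):
        df = simulate_cohort(n=800, seed=22)
        fit = fit_proportional_odds(
            df[list(COVARIATE_ORDER)], df["density_category"].to_numpy()
        )
        assert fit.converged
        assert np.all(np.diff(fit.ll_path) >= -1e-9)

    def test_wald_ci_reproduces_exp_beta_interval(self):
        df = simulate_cohort(n=800, seed=23)
        fit = fit_proportional_odds(
            df[list(COVARIATE_ORDER)], df["density_category"].to_numpy()
        )
        z = 1.959963984540054
        assert np.allclose(fit.or_ci_low, np.exp(fit.coef - z * fit.se))
        assert np.allclose(fit.or_ci_high, np.exp(fit.coef + z * fit.se))
        assert np.all(fit.or_ci_low <= fit.odds_ratios)
        assert np.all(fit.odds_ratios <= fit.or_ci_high)
        assert np.all(np.diff(fit.cutpoints) > 0)

    def test_matches_statsmodels_ordered_model(self):
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        df = simulate_cohort(n=1000, seed=24)
        X = df[["age", "hypertension", "female"]]
        y = df["density_category"]
        fit = fit_proportional_odds(X, y.to_numpy())
        ref = OrderedModel(y, X, distr="logit").fit(method="bfgs", disp=False)
        assert np.allclose(fit.coef, ref.params[:3].to_numpy(), atol=1e-4)

    def test_unobserved_category_rejected(self):
        y = np.array([1, 1, 3, 3, 3, 1])
        with pytest.raises(ValueError, match="collapse"):
            fit_proportional_odds(np.random.default_rng(0).normal(size=(6, 1)), y)

    def test_constant_column_rejected(self):
        y = np.array([1, 2, 1, 2, 1, 2])
        X = pd.DataFrame({"c": np.ones(6)})
        with pytest.raises(ValueError, match="constant"):
            fit_proportional_odds(X, y)


class TestLinear:
    def test_noiseless_recovery(self, rng):
        x = rng.normal(size=100)
        y = 2.0 * x
        fit = fit_linear_standardized(x.reshape(-1, 1), y)
        assert fit.coef[0] == pytest.approx(2.0 / y.std(ddof=1), rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_pseudoinverse_oracle(self, rng):
        X = rng.normal(size=(200, 5))
        y = X @ rng.normal(size=5) + rng.normal(size=200)
        fit = fit_linear_standardized(X, y)
        z = (y - y.mean()) / y.std(ddof=1)
        Xd = np.column_stack([np.ones(200), X])
        ref = np.linalg.pinv(Xd) @ z
        assert np.allclose(fit.coef, ref[1:], atol=1e-10)

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.normal(size=50)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="collinear"):
            fit_linear_standardized(X, rng.normal(size=50))

    def test_ci_brackets_beta(self, rng):
        X = rng.normal(size=(150, 3))
        y = X @ np.array([1.0, 0.0, -0.5]) + rng.normal(size=150)
        fit = fit_linear_standardized(X, y)
        assert np.all(fit.ci_low <= fit.coef) and np.all(fit.coef <= fit.ci_high)


class TestRestrictionAndTransforms:
    def test_all_flags_zero_is_identity(self):
        df = pd.DataFrame({"chd": [0, 0], "cva": [0, 0], "lipid_med": [0, 0], "v": [1, 2]})
        out, removed = restrict_sensitivity(df)
        assert removed == 0
        pd.testing.assert_frame_equal(out, df)

    def test_all_flags_one_empties_table_and_fit_refuses(self):
        df = pd.DataFrame({"chd": [1, 1], "cva": [0, 1], "lipid_med": [0, 0],
                           "x": [1.0, 2.0], "density_category": [1, 2]})
        out, removed = restrict_sensitivity(df)
        assert removed == 2 and len(out) == 0
        with pytest.raises(ValueError):
            fit_proportional_odds(out[["x"]], out["density_category"].to_numpy())

    def test_matches_row_filter_oracle(self, rng):
        n = 2464
        df = pd.DataFrame(
            {
                "chd": (rng.random(n) < 0.092) * 1,
                "cva": (rng.random(n) < 0.063) * 1,
                "lipid_med": (rng.random(n) < 0.244) * 1,
            }
        )
        out, removed = restrict_sensitivity(df)
        keep_oracle = [
            i for i in range(n)
            if not (df.loc[i, "chd"] or df.loc[i, "cva"] or df.loc[i, "lipid_med"])
        ]
        assert len(out) == len(keep_oracle)
        assert removed == n - len(keep_oracle)
        # under independent flags the retained fraction approximates the product form
        expect = (1 - 0.092) * (1 - 0.063) * (1 - 0.244)
        assert len(out) / n == pytest.approx(expect, abs=0.03)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="chd"):
            restrict_sensitivity(pd.DataFrame({"x": [1]}))

    def test_ln_transform(self):
        assert ln_transform([0.0], offset=1.0)[0] == 0.0
        assert ln_transform([232.0])[0] == pytest.approx(np.log(232), abs=1e-12)
        with pytest.raises(ValueError):
            ln_transform([-5.0])


class TestDescribe:
    def test_binary_count_percent(self):
        df = pd.DataFrame({"flag": [1] * 742 + [0] * 258})
        out = describe_cohort(df).set_index("variable")
        assert out.loc["flag", "summary"] == "742 (74.2)"

    def test_constant_column_sd_zero(self):
        df = pd.DataFrame({"c": np.full(10, 7.0)})
        out = describe_cohort(df).set_index("variable")
        assert out.loc["c", "stat2"] == 0.0

    def test_skewed_column_median_iqr(self, rng):
        df = pd.DataFrame({"v": rng.lognormal(4, 1, size=5000)})
        out = describe_cohort(df, skewed=["v"]).set_index("variable")
        assert out.loc["v", "kind"] == "skewed"
        assert out.loc["v", "stat1"] == pytest.approx(np.exp(4), rel=0.1)
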