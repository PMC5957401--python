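import numpy as np
import pandas as pd
import pytest
from scipy import linalg, stats

from mldendro.lmm import (
    ARMACorrelation,
    NestedLMM,
    RandomStructure,
    acf_resid,
    arma_corr,
    info_criteria,
    lr_test,
    var_const_power,
)


def one_way_data(g=6, n=8, mu=5.0, sd_b=1.2, sd_w=0.7, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(g):
        b = rng.normal(0, sd_b)
        for j in range(n):
            rows.append((mu + b + rng.normal(0, sd_w), j, str(i)))
    return pd.DataFrame(rows, columns=["y", "year", "g"])


def anova_reml_oracle(df):
    """Closed-form REML estimators for the balanced one-way layout."""
    groups = [g["y"].to_numpy() for _, g in df.groupby("g")]
    g, n = len(groups), len(groups[0])
    means = np.array([x.mean() for x in groups])
    msw = sum(((x - x.mean()) ** 2).sum() for x in groups) / (g * (n - 1))
    msb = n * ((means - means.mean()) ** 2).sum() / (g - 1)
    if msb > msw:
        return means.mean(), msw, (msb - msw) / n
    # boundary: zero between-group variance, all observations pooled
    y = np.concatenate(groups)
    return means.mean(), ((y - y.mean()) ** 2).sum() / (g * n - 1), 0.0


class TestRemlOracle:
    @pytest.mark.parametrize("seed,sd_b", [(0, 1.2), (1, 0.4), (2, 0.0)])
    def test_balanced_one_way_matches_anova(self, seed, sd_b):
        df = one_way_data(seed=seed, sd_b=sd_b)
        res = NestedLMM(
            df, "y", [], groups=["g"],
            random=RandomStructure("diag", ("(Intercept)",)),
        ).fit()
        mu, s2w, s2b = anova_reml_oracle(df)
        assert res.params["(Intercept)"] == pytest.approx(mu, rel=1e-6)
        assert res.sigma2 == pytest.approx(s2w, rel=1e-6)
        est_b = res.varcomps["g"]["(Intercept)"] ** 2
        if s2b > 1e-12:
            assert est_b == pytest.approx(s2b, rel=1e-6)
        else:
            assert est_b < 1e-6

    def test_profiled_loglik_consistency(self):
        df = one_way_data()
        model = NestedLMM(
            df, "y", [], groups=["g"],
            random=RandomStructure("diag", ("(Intercept)",)),
        )
        res = model.fit()
        assert res.llf == pytest.approx(model.loglik(res.theta), abs=1e-8)

    def test_mixedlm_cross_check(self):
        """statsmodels MixedLM as independent REML oracle (unbalanced)."""
        import statsmodels.formula.api as smf

        df = one_way_data(g=8, n=6, seed=3)
        df = df.drop(index=[1, 7, 13]).reset_index(drop=True)  # unbalance
        sm_res = smf.mixedlm("y ~ 1", df, groups=df["g"]).fit(reml=True)
        res = NestedLMM(
            df, "y", [], groups=["g"],
            random=RandomStructure("diag", ("(Intercept)",)),
        ).fit()
        assert res.params["(Intercept)"] == pytest.approx(
            sm_res.params["Intercept"], rel=1e-5
        )
        assert res.sigma2 == pytest.approx(sm_res.scale, rel=1e-4)
        assert res.varcomps["g"]["(Intercept)"] ** 2 == pytest.approx(
            float(sm_res.cov_re.iloc[0, 0]), rel=1e-3, abs=1e-8
        )

    def test_ols_limit_exact(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"y": rng.normal(size=40), "year": np.arange(40)})
        df["t"] = np.arange(40.0)
        res = NestedLMM(df, "y", ["t"], groups=[]).fit()
        X = np.column_stack([np.ones(40), df["t"]])
        beta = np.linalg.lstsq(X, df["y"], rcond=None)[0]
        np.testing.assert_allclose(res.params.to_numpy(), beta, rtol=1e-12)
        # maximised Gaussian log-likelihood, k = coefficients + sigma
        rss = ((df["y"] - X @ beta) ** 2).sum()
        llf = -0.5 * 40 * (np.log(2 * np.pi * rss / 40) + 1)
        assert res.llf == pytest.approx(llf, abs=1e-10)
        assert res.k_params == 3
        assert res.df["t"] == 38


class TestNoiselessIdentifiability:
    def test_zero_noise_recovers_beta_exactly(self):
        from mldendro.synthetic import SimDesign, gen_growth_frame

        design = SimDesign(
            years=(1986, 2005),
            sd_intercept=(0, 0, 0), sd_logcsx=(0, 0, 0), sd_time=(0, 0, 0),
            sigma=0.0, seed=1,
        )
        df = gen_growth_frame(design)
        res = NestedLMM(
            df, "log(x)", ["log(csx)", "log(time)"], groups=["plot", "tree", "sample"]
        ).fit()
        b0, b1, b2 = design.beta
        np.testing.assert_allclose(
            res.params.to_numpy(), [b0, b1, -b2], atol=1e-6
        )
        assert np.all(np.abs(res.resid) < 1e-6)


class TestArmaCorr:
    def test_ar1_reduction(self):
        phi = 0.55
        C = arma_corr(phi=[phi], n=6)
        lags = np.abs(np.subtract.outer(np.arange(6), np.arange(6)))
        np.testing.assert_allclose(C, phi**lags, rtol=1e-10)

    def test_arma11_closed_form(self):
        phi, theta = 0.5, 0.3
        rho1 = (1 + phi * theta) * (phi + theta) / (1 + 2 * phi * theta + theta**2)
        C = arma_corr(phi=[phi], theta=[theta], n=4)
        assert C[0, 1] == pytest.approx(rho1, rel=1e-10)
        assert C[0, 2] == pytest.approx(phi * rho1, rel=1e-10)
        assert rho1 == pytest.approx(0.66187, abs=5e-6)

    def test_white_noise_identity(self):
        np.testing.assert_array_equal(arma_corr(n=5), np.eye(5))

    def test_nonstationary_rejected(self):
        with pytest.raises(ValueError, match="stationary"):
            arma_corr(phi=[1.01], n=4)


class TestVarConstPower:
    @pytest.mark.parametrize(
        "rho1,rho2,nu,expected",
        [(1.5, 0.0, 7.0, 2.5), (0.0, 1.0, 3.0, 3.0), (2.0, 0.5, 9.0, 5.0)],
    )
    def test_multipliers(self, rho1, rho2, nu, expected):
        assert var_const_power(rho1, rho2, [nu])[0] == pytest.approx(expected)

    def test_zero_multiplier_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            var_const_power(0.0, 1.0, [0.0])


class TestNormalizedResiduals:
    def test_identity_covariance_scales_by_sigma(self):
        df = one_way_data()
        res = NestedLMM(
            df, "y", [], groups=["g"],
            random=RandomStructure("diag", ("(Intercept)",)),
        ).fit()
        np.testing.assert_allclose(
            res.resid_normalized, res.resid / res.sigma, rtol=1e-10
        )

    def test_two_by_two_cholesky_whitening(self):
        # covariance [[1, .5], [.5, 1]], residuals (1, 1)
        L = np.linalg.cholesky(np.array([[1.0, 0.5], [0.5, 1.0]]))
        eps = linalg.solve_triangular(L, np.ones(2), lower=True)
        np.testing.assert_allclose(eps, [1.0, 0.57735], atol=5e-6)

    def test_ar1_fit_whitens_residuals(self):
        """AR(1) errors modelled with an AR(1) correlation leave the
        lag-1 autocorrelation of normalized residuals inside 1% bounds."""
        rng = np.random.default_rng(12)
        phi = 0.6
        rows = []
        for gi in range(6):
            mu = rng.normal(0, 1.0)
            e = np.zeros(120)
            e[0] = rng.normal(0, 1 / np.sqrt(1 - phi**2))
            for t in range(1, 120):
                e[t] = phi * e[t - 1] + rng.normal()
            for t in range(120):
                rows.append((mu + 0.5 * e[t], t, str(gi)))
        df = pd.DataFrame(rows, columns=["y", "year", "g"])
        res = NestedLMM(
            df, "y", [], groups=["g"],
            random=RandomStructure("diag", ("(Intercept)",)),
            correlation=ARMACorrelation(1, 0),
        ).fit()
        assert res.corr_params["phi"][0] == pytest.approx(phi, abs=0.1)
        table = res.acf(max_lag=5, alpha=0.01, normalized=True)
        assert abs(table["acf"][1]) < table["bound"][1]

    def test_arma_fit_never_below_independence(self):
        rng = np.random.default_rng(4)
        rows = []
        for gi in range(4):
            e = np.zeros(80)
            a_prev = rng.normal()
            for t in range(80):
                a = rng.normal()
                e[t] = (0.5 * e[t - 1] if t else 0.0) + 0.3 * a_prev + a
                a_prev = a
            for t in range(80):
                rows.append((1.0 + 0.4 * e[t], t, str(gi)))
        df = pd.DataFrame(rows, columns=["y", "year", "g"])
        kw = dict(groups=["g"], random=RandomStructure("diag", ("(Intercept)",)))
        base = NestedLMM(df, "y", [], **kw).fit()
        armafit = NestedLMM(
            df, "y", [], correlation=ARMACorrelation(1, 1), **kw
        ).fit()
        assert armafit.llf >= base.llf - 1e-8


class TestAcf:
    def test_lag_zero_is_one(self):
        rng = np.random.default_rng(0)
        table = acf_resid([rng.normal(size=50)], max_lag=5)
        assert table["acf"][0] == pytest.approx(1.0)

    def test_white_noise_inside_bounds(self):
        rng = np.random.default_rng(123)
        groups = [rng.normal(size=125) for _ in range(8)]
        table = acf_resid(groups, max_lag=10, alpha=0.01)
        inside = (table["acf"].abs() <= table["bound"])[1:]
        assert inside.sum() >= 9

    def test_ar1_autocorrelation_estimated(self):
        rng = np.random.default_rng(7)
        phi, n = 0.7, 2000
        e = np.zeros(n)
        e[0] = rng.normal(0, 1 / np.sqrt(1 - phi**2))
        for t in range(1, n):
            e[t] = phi * e[t - 1] + rng.normal()
        table = acf_resid([e], max_lag=3)
        assert table["acf"][1] == pytest.approx(phi, abs=0.05)

    def test_invalid_lags(self):
        with pytest.raises(ValueError):
            acf_resid([np.ones(10)], max_lag=0)
        with pytest.raises(ValueError):
            acf_resid([np.ones(10)], max_lag=10)


class TestInformationCriteria:
    def test_reml_conventions(self):
        aic, bic, _ = info_criteria(-699.5963, 13, 988, 3, "REML")
        assert aic == pytest.approx(1425.1926, abs=1e-4)
        assert bic == pytest.approx(1488.797, abs=1e-3)

    def test_ml_conventions(self):
        aic, bic, _ = info_criteria(-758.9235, 4, 988, 3, "ML")
        assert aic == pytest.approx(1525.847, abs=1e-3)
        assert bic == pytest.approx(1545.418, abs=1e-3)

    def test_degenerate_zero(self):
        aic, _, _ = info_criteria(0.0, 0, 10, 1, "ML")
        assert aic == 0.0


class TestLrTest:
    def test_statistic_from_loglik_pair(self):
        stat, df, p = lr_test((-699.5963, 13), (-758.9235, 4))
        assert stat == pytest.approx(118.6544, abs=2e-4)
        assert df == 9
        assert p < 1e-4

    def test_chi2_two_df_tail(self):
        stat, df, p = lr_test((-17.23966, 5), (-18.21635, 3))
        assert stat == pytest.approx(1.953366, abs=2e-4)
        assert df == 2
        assert p == pytest.approx(np.exp(-stat / 2), rel=1e-12)
        assert p == pytest.approx(0.3766, abs=2e-4)

    def test_identical_models_zero(self):
        stat, _, p = lr_test((-10.0, 5), (-10.0, 3))
        assert stat == 0.0 and p == 1.0

    def test_non_nested_rejected(self):
        with pytest.raises(ValueError, match="nested"):
            lr_test((-10.0, 3), (-12.0, 3))


class TestConditionalTTests:
    @pytest.mark.parametrize(
        "est,se,t_exp,p_exp",
        [
            (-3.171448, 1.4210373, -2.231784, 0.0259),
            (1.398107, 0.3585760, 3.899055, 0.0001),
            (-0.953834, 0.2296603, -4.153239, 0.0000),
        ],
    )
    def test_t_statistics_and_pvalues(self, est, se, t_exp, p_exp):
        t = est / se
        assert t == pytest.approx(t_exp, abs=2e-4)
        p = 2 * stats.t.sf(abs(t), 978)
        assert p == pytest.approx(p_exp, abs=5e-4)

    def test_zero_estimate(self):
        assert 2 * stats.t.sf(0.0, 100) == 1.0

    def test_containment_df_from_fit(self):
        """Covariates varying within innermost groups get N - m - p DF."""
        from mldendro.synthetic import SimDesign, gen_growth_frame

        df = gen_growth_frame(SimDesign(years=(1986, 2005), seed=2))
        res = NestedLMM(
            df, "log(x)", ["log(csx)", "log(time)"],
            groups=["plot", "tree", "sample"],
        ).fit()
        n, m = len(df), 8
        assert (res.df == n - m - 2).all()


class TestErrors:
    def test_singular_design_rejected(self):
        df = pd.DataFrame({"y": np.arange(6.0), "a": np.ones(6), "year": range(6)})
        with pytest.raises(ValueError, match="singular"):
            NestedLMM(df, "y", ["a"], groups=[])

    def test_nonfinite_response_rejected(self):
        df = pd.DataFrame({"y": [0.0, -1.0, 2.0], "year": range(3)})
        with pytest.raises(ValueError, match="log"):
            NestedLMM(df, "log(y)", [], groups=[])
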