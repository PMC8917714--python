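"""FIML estimation: likelihood kernel, optimizer, reference fits, LRT.

The cross-check oracle here is an independently coded Wishart ML
discrepancy, F(theta) = log|Sigma(theta)| + tr(S Sigma^-1) - log|S| - p,
assembled from explicit matrix products and minimized by scipy with
finite-difference gradients — a different objective derivation and code
path from the package's casewise FIML likelihood with analytic gradients.
"""

import numpy as np
import pytest
from scipy import optimize, stats
from scipy.stats import multivariate_normal

from gbb8.data import ItemDataset
from gbb8.model import (CFAModel, GroupData, _loglik_mu_sigma,
                        _make_group_data, _Pattern, fit_baseline,
                        fit_saturated, fiml_loglik, lrt)
from gbb8.specs import build_model, build_template, implied_moments


# ----------------------------------------------------------------------
# Likelihood kernel
# ----------------------------------------------------------------------
class TestLoglikKernel:
    def test_standard_normal_single_case(self):
        # one variable, one case x=0 under N(0,1): log density = -log(2 pi)/2
        gd = GroupData("g", [_Pattern(np.array([0]), 1, np.zeros(1),
                                      np.zeros((1, 1)))], n=1, p=1)
        ll = _loglik_mu_sigma(gd, np.zeros(1), np.eye(1))
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    def test_missing_item_contributes_marginal_density(self, rng):
        # dropping a coordinate of a Gaussian marginalizes it
        mu = rng.normal(size=8)
        A = rng.normal(size=(8, 8)) * 0.2 + np.eye(8)
        Sigma = A @ A.T
        x = rng.normal(size=8)
        obs = np.arange(7)  # item 8 missing
        gd = GroupData("g", [_Pattern(obs, 1, x[obs],
                                      np.zeros((7, 7)))], n=1, p=8)
        ll = _loglik_mu_sigma(gd, mu, Sigma)
        expected = multivariate_normal(mu[obs], Sigma[np.ix_(obs, obs)]).logpdf(x[obs])
        assert ll == pytest.approx(expected, rel=1e-10)

    def test_complete_data_equals_sufficient_statistic_form(self, rng):
        # casewise sum == n-weighted moment form on complete data
        X = rng.normal(2, 1, size=(50, 8))
        gd = _make_group_data(X, "g")
        mu = X.mean(0) + 0.1
        Sigma = np.cov(X.T, ddof=0) + 0.3 * np.eye(8)
        ll = _loglik_mu_sigma(gd, mu, Sigma)
        direct = multivariate_normal(mu, Sigma).logpdf(X).sum()
        assert ll == pytest.approx(direct, rel=1e-10)

    def test_fiml_equals_complete_data_ml(self, complete_single_group):
        # with nothing missing, FIML is exactly the complete-data likelihood
        spec = build_model("second_order")
        model = CFAModel.from_dataset(complete_single_group, spec)
        res = model.fit()
        mu, Sigma = implied_moments(spec, res.params[0])
        X = complete_single_group.responses.to_numpy()
        direct = multivariate_normal(mu, Sigma).logpdf(X).sum()
        assert res.llf == pytest.approx(direct, rel=1e-8)


# ----------------------------------------------------------------------
# Saturated and baseline reference fits
# ----------------------------------------------------------------------
class TestReferenceFits:
    def test_saturated_complete_data_is_sample_moments(self, rng):
        X = rng.normal(1, 2, size=(60, 8))
        gd = _make_group_data(X, "g")
        sat = fit_saturated([gd])
        mu, Sigma = sat.moments[0]
        assert np.allclose(mu, X.mean(0))
        assert np.allclose(Sigma, np.cov(X.T, ddof=0))

    def test_saturated_em_matches_monotone_closed_form(self, rng):
        # 3-variable monotone missingness: the factored-likelihood (regression)
        # estimates are the exact ML solution; EM must reproduce them
        n = 60
        A = np.array([[1.0, 0.0, 0.0], [0.5, 1.0, 0.0], [0.3, 0.4, 1.0]])
        X = rng.normal(size=(n, 3)) @ A.T + [1.0, 2.0, 3.0]
        X[40:, 2] = np.nan
        X[50:, 1] = np.nan

        # factored-likelihood oracle (Anderson): x1; x2|x1 on 50; x3|x1,x2 on 40
        mu = np.zeros(3)
        S = np.zeros((3, 3))
        mu[0] = X[:, 0].mean()
        S[0, 0] = X[:, 0].var()
        sub = X[:50]
        b = np.polyfit(sub[:, 0], sub[:, 1], 1)
        resid = sub[:, 1] - np.polyval(b, sub[:, 0])
        mu[1] = b[0] * mu[0] + b[1]
        S[0, 1] = S[1, 0] = b[0] * S[0, 0]
        S[1, 1] = resid.var() + b[0] ** 2 * S[0, 0]
        sub = X[:40]
        Z = np.column_stack([np.ones(40), sub[:, 0], sub[:, 1]])
        coef, *_ = np.linalg.lstsq(Z, sub[:, 2], rcond=None)
        resid = sub[:, 2] - Z @ coef
        mu[2] = coef[0] + coef[1] * mu[0] + coef[2] * mu[1]
        S[0, 2] = S[2, 0] = coef[1] * S[0, 0] + coef[2] * S[0, 1]
        S[1, 2] = S[2, 1] = coef[1] * S[0, 1] + coef[2] * S[1, 1]
        S[2, 2] = resid.var() + np.array([coef[1], coef[2]]) @ S[:2, :2] @ \
            np.array([coef[1], coef[2]])

        gd = _make_group_data(X, "g")
        sat = fit_saturated([gd], tol=1e-12, maxiter=2000)
        mu_em, S_em = sat.moments[0]
        assert np.allclose(mu_em, mu, atol=1e-5)
        assert np.allclose(S_em, S, atol=1e-4)

    def test_saturated_dominates_structured_dominates_baseline(self, default_data):
        spec = build_model("second_order")
        model = CFAModel.from_dataset(default_data, spec)
        res = model.fit()
        assert model.saturated.llf >= res.llf >= model.baseline.llf

    def test_baseline_df_is_28_per_group(self, complete_single_group):
        model = CFAModel.from_dataset(complete_single_group,
                                      build_model("second_order"))
        assert model.baseline.df == 28

    def test_baseline_chi2_vanishes_on_diagonal_data(self, rng):
        X = np.round(np.clip(rng.normal(2, 1, size=(5000, 8)), 0, 4))
        import pandas as pd
        from gbb8 import instrument
        data = ItemDataset(pd.DataFrame(X, columns=list(instrument.ITEM_NAMES)))
        model = CFAModel.from_dataset(data, build_model("one_factor"))
        chi2_b = 2 * (model.saturated.llf - model.baseline.llf)
        # independent items: baseline fits nearly perfectly (noise-level chi2)
        assert chi2_b < model.baseline.df + 4 * np.sqrt(2 * model.baseline.df)


# ----------------------------------------------------------------------
# Structured fits
# ----------------------------------------------------------------------
class TestFitModel:
    def test_perfect_fit_on_model_implied_moments(self):
        # feeding implied moments back as data yields chi2 ~ 0
        spec = build_model("second_order")
        tmpl = build_template(spec)
        x = tmpl.pack([{
            "loading": np.full(8, 0.9), "nu": np.full(8, 1.7),
            "theta": np.full(8, 0.5), "lambda2": np.full(4, 0.95),
            "psi_d": np.full(4, 0.3), "phi": np.array([0.8]),
            "tau": np.zeros(4), "alpha": np.zeros(1),
        }])
        mu, Sigma = implied_moments(spec, tmpl.unpack(x)[0])
        model = CFAModel.from_moments({"all": (600, mu, Sigma)}, spec)
        res = model.fit()
        assert res.chi2 <= 1e-4
        assert res.df == 16

    def test_reidentification_leaves_loglik_invariant(self, complete_single_group):
        # choosing the other item of each pair as the marker is a
        # reparameterization: the optimum log-likelihood cannot change
        spec = build_model("second_order")
        res = CFAModel.from_dataset(complete_single_group, spec).fit()
        swapped = {s: (b, a) for s, (a, b) in complete_single_group.subscales.items()}
        items = tuple(i for pair in swapped.values() for i in pair)
        data2 = ItemDataset(complete_single_group.df, item_names=items,
                            subscales=swapped)
        res2 = CFAModel.from_dataset(data2, build_model(
            "second_order", item_names=items, subscales=swapped)).fit()
        assert res.llf == pytest.approx(res2.llf, abs=1e-6 * abs(res.llf))

    def test_parameter_recovery_from_large_sample(self):
        from gbb8.simulate import GeneratorConfig, generate_dataset
        cfg = GeneratorConfig(group_sizes={"all": 20_000}, group_var="grp",
                              missing_rate=0.0, covariate_spec=(),
                              extra_labels={}, seed=7)
        data = generate_dataset(cfg)
        res = CFAModel.from_dataset(data, build_model("second_order")).fit()
        std = res.standardized_loadings()[0]
        assert np.abs(std["loading"] - 0.88).max() < 0.05
        assert np.abs(std["lambda2"] - 0.90).max() < 0.05

    def test_standard_errors_have_plausible_scale(self, complete_single_group):
        res = CFAModel.from_dataset(complete_single_group,
                                    build_model("one_factor")).fit()
        bse = res.bse
        assert bse.shape == (res.n_free,)
        assert (bse > 0).all() and (bse < 1).all()

    def test_summary_mentions_fit_statistics(self, complete_single_group):
        res = CFAModel.from_dataset(complete_single_group,
                                    build_model("second_order")).fit()
        text = res.summary()
        assert "chi2(16)" in text
        assert "log-likelihood" in text


# ----------------------------------------------------------------------
# Independent Wishart-discrepancy oracle
# ----------------------------------------------------------------------
def _oracle_fit_second_order(S, p=8):
    """Brute-force normal-theory ML fit of the second-order structure by
    minimizing the Wishart discrepancy with finite-difference gradients."""
    fac = np.repeat(np.arange(4), 2)

    def sigma_of(theta):
        lam1 = np.ones(p)
        lam1[[1, 3, 5, 7]] = theta[0:4]
        lam2 = np.ones(4)
        lam2[1:] = theta[4:7]
        phi = theta[7]
        psi_d = theta[8:12]
        th = theta[12:20]
        B = np.outer(lam2, lam2) * phi + np.diag(psi_d)
        L1 = np.zeros((p, 4))
        L1[np.arange(p), fac] = lam1
        return L1 @ B @ L1.T + np.diag(th)

    sign, logdet_s = np.linalg.slogdet(S)

    def F(theta):
        Sig = sigma_of(theta)
        sgn, ld = np.linalg.slogdet(Sig)
        if sgn <= 0:
            return 1e6
        return ld + np.trace(np.linalg.solve(Sig, S)) - logdet_s - p

    x0 = np.concatenate([np.ones(7), [0.5], np.full(4, 0.5),
                         np.diag(S) / 2])
    bounds = [(None, None)] * 7 + [(1e-4, None)] * 13
    res = optimize.minimize(F, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxfun": 200_000, "ftol": 1e-15,
                                     "gtol": 1e-10})
    res = optimize.minimize(F, res.x, method="L-BFGS-B", bounds=bounds,
                            options={"maxfun": 200_000, "ftol": 1e-15,
                                     "gtol": 1e-10})
    return res.fun, res.x, sigma_of(res.x)


class TestOracleAgreement:
    def test_chi2_and_estimates_match_independent_implementation(
            self, complete_single_group):
        spec = build_model("second_order")
        model = CFAModel.from_dataset(complete_single_group, spec)
        res = model.fit()
        X = complete_single_group.responses.to_numpy()
        S = np.cov(X.T, ddof=0)
        F_min, theta, Sigma_oracle = _oracle_fit_second_order(S)
        n = len(X)
        assert res.chi2 == pytest.approx(n * F_min, abs=1e-3)
        # estimates: free first-order loadings, second-order loadings, variances
        g = res.params[0]
        free_lam1 = g["loading"][[1, 3, 5, 7]]
        assert np.allclose(free_lam1, theta[0:4], atol=1e-3)
        assert np.allclose(g["lambda2"][1:], theta[4:7], atol=1e-3)
        assert np.allclose(g["theta"], theta[12:20], atol=1e-3)
        _, Sigma_mine = implied_moments(spec, g)
        assert np.allclose(Sigma_mine, Sigma_oracle, atol=1e-3)


# ----------------------------------------------------------------------
# Likelihood-ratio testing
# ----------------------------------------------------------------------
class TestLRT:
    def test_chi_square_difference_hand_example(self):
        # chi2 (13.5, 10), df (8, 5): delta = 3.5 on 3 df
        class _Stub:
            def __init__(self, chi2, df):
                self.chi2, self.df = chi2, df
        out = lrt(_Stub(13.5, 8), _Stub(10.0, 5))
        assert out.dchi2 == pytest.approx(3.5)
        assert out.ddf == 3
        assert out.pvalue == pytest.approx(stats.chi2.sf(3.5, 3), abs=1e-12)
        assert out.pvalue == pytest.approx(0.3208, abs=2e-4)

    def test_identical_fits_give_p_one(self):
        class _Stub:
            def __init__(self, chi2, df):
                self.chi2, self.df = chi2, df
        out = lrt(_Stub(10.0, 8), _Stub(10.0, 5))
        assert out.dchi2 == 0.0
        assert out.pvalue == 1.0

    def test_non_nested_direction_rejected(self):
        class _Stub:
            def __init__(self, chi2, df):
                self.chi2, self.df = chi2, df
        with pytest.raises(ValueError):
            lrt(_Stub(10.0, 5), _Stub(5.0, 5))

    def test_nested_chi2_monotone_on_real_fits(self, complete_single_group):
        # the one-factor model is nested in neither, but the second-order
        # model is nested in the correlated model: chi2 must not decrease
        corr = CFAModel.from_dataset(complete_single_group,
                                     build_model("correlated")).fit()
        second = CFAModel.from_dataset(complete_single_group,
                                       build_model("second_order")).fit()
        out = lrt(second, corr)
        assert out.ddf == 2
        assert out.dchi2 >= 0
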