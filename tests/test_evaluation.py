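"""Criteria, model lists, predictive checks and cross-validation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import logsumexp

import soilspde as sp


def iid_fit(seed=0, n=100, beta1=0.6, sigma_obs=0.4, fixed=True,
            covariates=("som",), family="lognormal"):
    """Fast non-spatial fit on iid lognormal data."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    noise = rng.standard_normal(n)
    y = np.exp(1.5 + beta1 * x + sigma_obs * noise)
    df = pd.DataFrame({"conc": y, "som": x, "noise_cov": rng.standard_normal(n)})
    spec = sp.ModelSpec(
        family=family, covariates=list(covariates),
        include_spatial=False, include_state=False,
        fixed_hyper={"sigma_obs": sigma_obs} if fixed else {},
    )
    return sp.fit(spec, df, None, seed=seed), df


class TestCriteria:
    def test_waic_matches_bruteforce_from_draws(self):
        fit, df = iid_fit(seed=1)
        n_draws = 2000
        draws = fit.sample_posterior(n_draws, seed=3)
        beta = draws["beta"]
        # independent recomputation with scipy from the same draws
        X = np.column_stack([np.ones(len(df)), df["som"]])
        eta = beta @ X.T
        y = df["conc"].to_numpy()
        L = stats.lognorm.logpdf(y[None, :], s=0.4, scale=np.exp(eta))
        lppd = logsumexp(L, axis=0) - np.log(n_draws)
        p_eff = L.var(axis=0, ddof=1)
        expected = -2 * np.sum(lppd - p_eff)
        assert sp.waic(fit, n_draws, seed=3) == pytest.approx(expected, abs=1e-6)

    def test_noise_covariate_raises_waic(self):
        wins = 0
        for seed in range(20):
            f_true, df = iid_fit(seed=seed, covariates=("som",))
            f_noise, _ = iid_fit(seed=seed, covariates=("som", "noise_cov"))
            if sp.waic(f_noise, 800, seed=seed) > sp.waic(f_true, 800, seed=seed):
                wins += 1
        assert wins >= 14  # noise covariate worsens WAIC in >= 70% of runs

    def test_lcpo_orders_good_vs_bad_model(self):
        f_good, df = iid_fit(seed=5, beta1=1.5, sigma_obs=0.2)
        spec0 = sp.ModelSpec(covariates=[], include_spatial=False,
                             include_state=False, fixed_hyper={"sigma_obs": 0.2})
        f_int = sp.fit(spec0, df, None, seed=5)
        assert sp.lcpo(f_good) < sp.lcpo(f_int)

    def test_lcpo_invariant_to_observation_order(self):
        fit, df = iid_fit(seed=7)
        perm = np.random.default_rng(0).permutation(len(df))
        fit_p = sp.fit(fit.spec, df.iloc[perm].reset_index(drop=True), None, seed=7)
        a = sp.cpo(fit)
        b = sp.cpo(fit_p)
        np.testing.assert_allclose(np.sort(a), np.sort(b), rtol=1e-8)
        assert sp.lcpo(fit) == pytest.approx(sp.lcpo(fit_p), abs=1e-8)

    def test_dic_effective_parameters_nonnegative_on_null_data(self):
        fit, _ = iid_fit(seed=9, beta1=0.0)
        L = fit.pointwise_loglik(1000)
        d_bar = np.mean(-2 * L.sum(axis=1))
        eta_hat = fit.asm.A @ fit.latent_mean()
        d_hat = -2 * fit.asm.loglik(eta_hat, fit.hyper_mean()).sum()
        assert d_bar - d_hat >= 0.0


class TestModelList:
    def make_list(self):
        return pd.DataFrame(
            {
                "name": ["m1", "m2", "m3"],
                "family": ["lognormal"] * 3,
                "covariates": ["som", "som noise_cov", ""],
                "include_spatial": [False] * 3,
                "include_state": [False] * 3,
            }
        )

    def test_three_models_one_top(self):
        _, df = iid_fit(seed=2)
        report = sp.fit_model_list(self.make_list(), df, None, seed=2)
        assert len(report.table) == 3
        assert report.table["selected_top"].sum() == 1
        assert (report.table["waic"].diff().dropna() >= 0).all()

    def test_duplicate_names_rejected(self):
        _, df = iid_fit(seed=2)
        bad = self.make_list()
        bad.loc[2, "name"] = "m1"
        with pytest.raises(ValueError, match="duplicate"):
            sp.fit_model_list(bad, df, None)

    def test_unknown_covariate_rejected(self):
        _, df = iid_fit(seed=2)
        bad = self.make_list()
        bad.loc[0, "covariates"] = "no_such"
        with pytest.raises(ValueError, match="no_such"):
            sp.fit_model_list(bad, df, None)

    def test_malformed_row_reports_number(self):
        bad = self.make_list()
        bad.loc[1, "family"] = "weibull"
        with pytest.raises(ValueError, match="row 1"):
            sp.fit_model_list(bad, pd.DataFrame({"conc": [1.0]}), None)

    def test_csv_roundtrip(self, tmp_path):
        _, df = iid_fit(seed=2)
        p = tmp_path / "models.csv"
        self.make_list().to_csv(p, index=False)
        report = sp.fit_model_list(p, df, None, seed=2)
        assert set(report.fits) == {"m1", "m2", "m3"}


class TestPpc:
    def test_replicate_count(self):
        fit, _ = iid_fit(seed=3)
        s = sp.posterior_predictive_check(fit, n=1000, seed=1)
        for stat in ("mean", "median", "variance", "q90"):
            assert len(s.simulated[stat]) == 1000
        assert s.n == 1000

    def test_statistics_reported(self):
        fit, _ = iid_fit(seed=3)
        s = sp.posterior_predictive_check(fit, n=300, seed=1)
        assert list(s.table["statistic"]) == ["mean", "median", "variance", "q90"]
        assert (s.table["ci_lower"] <= s.table["ci_upper"]).all()

    def test_designed_failure_variance_excluded(self):
        # a near-constant-response model cannot reproduce the observed spread
        rng = np.random.default_rng(8)
        y = np.exp(1.0 + 1.0 * rng.standard_normal(60))
        df = pd.DataFrame({"conc": y})
        spec = sp.ModelSpec(covariates=[], include_spatial=False,
                            include_state=False, fixed_hyper={"sigma_obs": 0.01})
        f = sp.fit(spec, df, None, seed=8)
        s = sp.posterior_predictive_check(f, n=400, seed=2)
        row = s.table.set_index("statistic").loc["variance"]
        assert not row["inside"]

    def test_plot_written(self, tmp_path):
        fit, _ = iid_fit(seed=3)
        s = sp.posterior_predictive_check(fit, n=200, seed=1)
        out = tmp_path / "ppc.png"
        sp.evaluation.plot_ppc(s, out)
        assert out.exists() and out.stat().st_size > 0


class TestCrossValidation:
    def test_loo_matches_conjugate_closed_form(self):
        # intercept-only Gaussian-on-log model with fixed noise: the
        # leave-one-out predictive density is available analytically
        rng = np.random.default_rng(12)
        n, s, v0 = 40, 0.5, 1.0 / 1e-4
        z = 1.2 + s * rng.standard_normal(n)
        df = pd.DataFrame({"conc": np.exp(z)})
        spec = sp.ModelSpec(covariates=[], include_spatial=False,
                            include_state=False, fixed_hyper={"sigma_obs": s})
        f = sp.fit(spec, df, None, seed=12)
        res = sp.cross_validate(f, "loo")
        for i in range(n):
            others = np.delete(z, i)
            prec = 1.0 / v0 + len(others) / s**2
            m = (others.sum() / s**2) / prec
            v = 1.0 / prec + s**2
            expected = stats.norm.logpdf(z[i], m, np.sqrt(v)) - z[i]
            assert res["scores"][i] == pytest.approx(expected, abs=1e-4)

    def test_score_count_and_mode_validation(self):
        fit, _ = iid_fit(seed=4)
        res = sp.cross_validate(fit, "loo")
        assert len(res["scores"]) == fit.n_obs
        with pytest.raises(ValueError):
            sp.cross_validate(fit, "xxx")
        with pytest.raises(ValueError):
            sp.cross_validate(fit, "lgo", group_size=fit.n_obs)

    def test_loo_vs_lgo_stability_on_weak_field(self, small_domain, small_boundary):
        # well-specified model with modest residual spatial structure:
        # scores barely move when small spatial neighbourhoods are removed
        # instead of single observations
        truth = sp.SyntheticTruth(
            beta0=2.0, beta=[0.4], range_true=150.0, sigma_true=0.2,
            sigma_state=0.05, sigma_obs=0.5, seed=3,
        )
        tab, _ = sp.simulate_survey(small_domain, 100, truth, seed=3)
        clean = sp.clean_survey(tab)
        scaled, _ = sp.standardize_covariates(clean, ["som"])
        clean["som"] = scaled["som"]
        boundary, _ = small_boundary
        pts = clean[["x_km", "y_km"]].to_numpy()
        mesh = sp.build_mesh(pts, boundary, sp.coarse_mesh_params(pts))
        f = sp.fit(sp.ModelSpec(covariates=["som"]), clean, mesh, seed=5)
        loo = sp.cross_validate(f, "loo")
        lgo = sp.cross_validate(f, "lgo", group_size=6)
        assert abs(loo["mean_score"] - lgo["mean_score"]) < 0.1

    def test_gamma_importance_weighting_agrees_with_refit(self):
        # the gamma family has no closed-form leave-out densities; the
        # importance-sampling estimate must agree with brute-force refits
        rng = np.random.default_rng(9)
        n = 40
        x = rng.standard_normal(n)
        y = rng.gamma(6.0, np.exp(1.2 + 0.5 * x) / 6.0)
        df = pd.DataFrame({"conc": y, "som": x})
        spec = sp.ModelSpec(family="gamma", covariates=["som"],
                            include_spatial=False, include_state=False)
        f = sp.fit(spec, df, None, seed=9)
        r_is = sp.cross_validate(f, "loo", n_draws=2000)
        r_refit = sp.cross_validate(f, "loo", n_draws=2000,
                                    refit_threshold=0.0)
        assert np.abs(r_is["scores"] - r_refit["scores"]).max() < 0.1
        assert np.all(sp.cpo(f) > 0)

    def test_lgo_groups_are_spatial_neighbours(self, toy_fit):
        res6 = sp.cross_validate(toy_fit, "lgo", group_size=6)
        res8 = sp.cross_validate(toy_fit, "lgo", group_size=8)
        # removing more neighbours can only lose information on average
        assert res8["mean_score"] <= res6["mean_score"] + 0.05


class TestSensitivity:
    def test_empty_variant_list_gives_baseline_row(self, toy_data, small_boundary):
        clean, _, _ = toy_data
        boundary, _ = small_boundary
        spec = sp.ModelSpec(covariates=["som"])
        out = sp.sensitivity_suite(spec, clean, [], boundary,
                                   range_estimate=150.0, n_draws=400)
        assert len(out) == 1 and out.loc[0, "label"] == "baseline"

    def test_unknown_variant_key_rejected(self, toy_data, small_boundary):
        clean, _, _ = toy_data
        boundary, _ = small_boundary
        with pytest.raises(ValueError, match="unknown"):
            sp.sensitivity_suite(
                sp.ModelSpec(covariates=["som"]), clean,
                [{"bogus": 1}], boundary, range_estimate=150.0,
            )

    def test_prior_precision_robustness(self, toy_data, small_boundary):
        # Table-style prior sweep: fixed-effect posteriors barely move
        clean, _, _ = toy_data
        boundary, _ = small_boundary
        spec = sp.ModelSpec(covariates=["som"])
        out = sp.sensitivity_suite(
            spec, clean,
            [
                {"intercept_prior": (0.0, 0.01), "fixed_prior": (0.0, 0.01)},
                {"intercept_prior": (0.0, 1e-6), "fixed_prior": (0.0, 1e-6)},
            ],
            boundary, range_estimate=150.0, n_draws=400,
        )
        base = out.loc[0, "beta_som"]
        assert np.abs(out["beta_som"] - base).max() < 0.05
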