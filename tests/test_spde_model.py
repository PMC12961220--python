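"""Statistical core: FEM assembly, PC priors, inference oracles, sampling."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from shapely.geometry import box

import soilspde as sp
from soilspde.spde_model import _Factor, assemble_fem


@pytest.fixture(scope="module")
def small_mesh():
    rng = np.random.default_rng(21)
    pts = rng.uniform([0, 0], [400, 300], (80, 2))
    pts[0] = [0.0, 150.0]
    pts[1] = [400.0, 150.0]
    return sp.build_mesh(pts, box(0, 0, 400, 300), sp.coarse_mesh_params(pts))


class TestFemAssembly:
    def test_stiffness_annihilates_constants(self, small_mesh):
        op = assemble_fem(small_mesh)
        ones = np.ones(op.n_nodes)
        assert np.abs(op.G @ ones).max() < 1e-10

    def test_mass_diagonal_sums_to_mesh_area(self, small_mesh):
        op = assemble_fem(small_mesh)
        assert op.C_diag.sum() == pytest.approx(
            small_mesh.triangle_areas().sum(), rel=1e-10
        )

    def test_degenerate_triangle_named(self):
        nodes = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [0.0, 1.0]])
        mesh = sp.Mesh(
            nodes=nodes,
            triangles=np.array([[0, 1, 3], [0, 1, 2]]),  # second is collinear
            inner=np.array([True, True]),
            boundary=box(0, 0, 2, 1),
        )
        with pytest.raises(ValueError, match="1"):
            assemble_fem(mesh)

    def test_marginal_variance_against_dense_inverse(self, small_mesh):
        # diag(Q^-1) at interior nodes should be close to sigma^2
        op = assemble_fem(small_mesh)
        sigma, range_ = 0.8, 120.0
        Q = op.precision(range_, sigma).toarray()
        var = np.diag(np.linalg.inv(Q))
        boundary = box(0, 0, 400, 300)
        interior = boundary.buffer(-60)
        import shapely

        mask = shapely.covers(interior, shapely.points(small_mesh.nodes))
        ratio = var[mask] / sigma**2
        assert np.median(np.abs(ratio - 1.0)) < 0.15

    def test_precision_positive_definite_across_hyperparameters(self, small_mesh):
        op = assemble_fem(small_mesh)
        for r in (30.0, 120.0, 600.0):
            for s in (0.1, 0.8, 3.0):
                _Factor(op.precision(r, s))  # raises if not SPD

    def test_prior_logdet_matches_dense(self, small_mesh):
        op = assemble_fem(small_mesh)
        ld = op.logdet_precision(150.0, 0.7)
        sign, ld_dense = np.linalg.slogdet(op.precision(150.0, 0.7).toarray())
        assert sign > 0
        assert ld == pytest.approx(ld_dense, rel=1e-8)

    def test_prior_field_correlation_at_range(self, small_mesh):
        # correlation between interior node pairs ~range apart is ~0.1
        op = assemble_fem(small_mesh)
        range_ = 120.0
        cov = np.linalg.inv(op.precision(range_, 1.0).toarray())
        sd = np.sqrt(np.diag(cov))
        corr = cov / np.outer(sd, sd)
        import shapely

        interior = box(0, 0, 400, 300).buffer(-50)
        mask = shapely.covers(interior, shapely.points(small_mesh.nodes))
        idx = np.where(mask)[0]
        d = np.linalg.norm(
            small_mesh.nodes[idx][:, None] - small_mesh.nodes[idx][None, :], axis=2
        )
        near = (np.abs(d - range_) < 15.0) & (d > 0)
        assert near.any()
        sel = corr[np.ix_(idx, idx)][near]
        assert np.abs(sel.mean() - 0.1) < 0.05


class TestPcPrior:
    def test_sigma_prior_calibration(self):
        p = sp.pc_prior("sigma", 0.5, 0.5)
        assert 1.0 - p.cdf(0.5) == pytest.approx(0.5, abs=1e-12)
        assert 1.0 - p.cdf(1.0) == pytest.approx(0.25, abs=1e-12)

    def test_range_prior_calibration(self):
        p = sp.pc_prior("range", 500.0, 0.5)
        assert p.cdf(500.0) == pytest.approx(0.5, abs=1e-12)
        assert p.cdf(250.0) == pytest.approx(0.25, abs=1e-12)

    @pytest.mark.parametrize("kind,u,alpha", [
        ("sigma", 0.5, 0.5), ("sigma", 1.0, 0.5), ("sigma", 0.1, 0.5),
        ("sigma", 0.5, 0.99), ("range", 500.0, 0.5), ("range", 300.0, 0.2),
    ])
    def test_density_integrates_to_one(self, kind, u, alpha):
        p = sp.pc_prior(kind, u, alpha)
        total, _ = integrate.quad(p.pdf, 0, np.inf, limit=200)
        assert total == pytest.approx(1.0, abs=1e-7)

    def test_quantile_cdf_roundtrip(self):
        p = sp.pc_prior("range", 400.0, 0.5)
        q = np.array([0.05, 0.3, 0.5, 0.9])
        np.testing.assert_allclose(p.cdf(p.quantile(q)), q, atol=1e-12)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            sp.pc_prior("sigma", 0.5, 1.5)

    def test_sampling_matches_cdf(self):
        p = sp.pc_prior("sigma", 0.5, 0.5)
        s = p.sample(20_000, seed=0)
        assert np.mean(s > 0.5) == pytest.approx(0.5, abs=0.01)


class TestRangeThreshold:
    def test_half_extent(self):
        pts = np.array([[0.0, 0], [1200.0, 5], [300.0, 2]])
        assert sp.default_range_threshold(pts) == pytest.approx(600.0)

    def test_ratio_is_two_for_any_input(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 750, (40, 2))
        ext = pts[:, 0].max() - pts[:, 0].min()
        assert ext / sp.default_range_threshold(pts) == pytest.approx(2.0)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            sp.default_range_threshold(np.array([[3.0, 1.0], [3.0, 2.0]]))


class TestConjugateOracle:
    """Non-spatial fits against closed-form Bayesian linear regression."""

    def fit_and_closed_form(self, iid_data, sigma_obs=0.4):
        spec = sp.ModelSpec(
            covariates=["som"], include_spatial=False, include_state=False,
            fixed_hyper={"sigma_obs": sigma_obs},
        )
        f = sp.fit(spec, iid_data, mesh=None, seed=1)
        z = np.log(iid_data["conc"].to_numpy())
        X = np.column_stack([np.ones(len(z)), iid_data["som"].to_numpy()])
        P0 = np.diag([1e-4, 1e-4])
        Pn = P0 + X.T @ X / sigma_obs**2
        mean = np.linalg.solve(Pn, X.T @ z / sigma_obs**2)
        return f, mean, Pn

    def test_posterior_mean_matches_closed_form(self, iid_data):
        f, mean, _ = self.fit_and_closed_form(iid_data)
        np.testing.assert_allclose(f.beta_mean(), mean, atol=1e-6)

    def test_posterior_sd_matches_closed_form(self, iid_data):
        f, _, Pn = self.fit_and_closed_form(iid_data)
        sd = np.sqrt(np.diag(np.linalg.inv(Pn)))
        draws = f.sample_posterior(20_000, seed=2)["beta"]
        np.testing.assert_allclose(draws.std(axis=0), sd, rtol=0.05)
        np.testing.assert_allclose(
            draws.mean(axis=0), f.beta_mean(),
            atol=float(4 * sd.max() / np.sqrt(20_000)),
        )

    def test_lognormal_conditional_matches_dense_gaussian_algebra(self, toy_fit):
        """The lognormal conditional at each grid point equals the posterior
        of a Gaussian model on log-responses, recomputed densely here."""
        asm = toy_fit.asm
        z = np.log(asm.y)
        A = asm.A.toarray()
        for g in np.argsort(toy_fit.grid_weights)[-3:]:
            cond = toy_fit.conditionals[g]
            s2 = cond.params["sigma_obs"] ** 2
            Q = asm.prior_precision(cond.params).toarray()
            H = Q + A.T @ A / s2
            mu = np.linalg.solve(H, A.T @ z / s2)
            np.testing.assert_allclose(cond.mu, mu, atol=1e-8)


class TestFitBehaviour:
    def test_nonpositive_response_rejected(self, iid_data):
        bad = iid_data.copy()
        bad.loc[0, "conc"] = -1.0
        with pytest.raises(ValueError, match="positive"):
            sp.fit(sp.ModelSpec(include_spatial=False, include_state=False),
                   bad, None)

    def test_singular_design_lists_aliased(self, iid_data):
        bad = iid_data.copy()
        bad["dup"] = bad["som"]
        with pytest.raises(ValueError, match="aliased"):
            sp.fit(
                sp.ModelSpec(covariates=["som", "dup"], include_spatial=False,
                             include_state=False),
                bad, None,
            )

    def test_unsupported_family_rejected(self):
        with pytest.raises(ValueError):
            sp.ModelSpec(family="weibull")

    def test_posterior_contraction_with_sample_size(self):
        rng = np.random.default_rng(11)
        widths = {100: [], 200: []}
        for seed in range(10):
            r = np.random.default_rng(seed)
            for n in (100, 200):
                x = r.standard_normal(n)
                y = np.exp(1.0 + 0.5 * x + 0.4 * r.standard_normal(n))
                df = pd.DataFrame({"conc": y, "som": x})
                f = sp.fit(
                    sp.ModelSpec(covariates=["som"], include_spatial=False,
                                 include_state=False),
                    df, None, seed=seed,
                )
                ci = f.beta_interval(2000, seed=seed)
                widths[n].append(np.mean(ci[:, 1] - ci[:, 0]))
        assert np.mean(widths[200]) <= np.mean(widths[100])


class TestSamplePosterior:
    def test_draw_count_and_reproducibility(self, toy_fit):
        d1 = sp.sample_posterior(toy_fit, 1000, seed=9)
        assert d1["latent"].shape[0] == 1000
        d2 = sp.sample_posterior(toy_fit, 1000, seed=9)
        np.testing.assert_array_equal(d1["latent"], d2["latent"])

    def test_invalid_count_rejected(self, toy_fit):
        with pytest.raises(ValueError):
            sp.sample_posterior(toy_fit, 0)

    def test_sample_mean_consistent_with_marginal_mean(self, toy_fit):
        d = sp.sample_posterior(toy_fit, 10_000, seed=13)
        beta = d["beta"]
        se = beta.std(axis=0) / np.sqrt(len(beta))
        diff = np.abs(beta.mean(axis=0) - toy_fit.beta_mean())
        assert np.all(diff <= 3.5 * se + 1e-3)


class TestSummary:
    def test_summary_json_structure(self, toy_fit, tmp_path):
        p = tmp_path / "fit.json"
        toy_fit.summary_to_json(p, n_draws=300, seed=1)
        import json

        rec = json.loads(p.read_text())
        assert set(rec["fixed_effects"]) == {"intercept", "som"}
        fe = rec["fixed_effects"]["som"]
        assert fe["ci_lower"] <= fe["mean"] <= fe["ci_upper"]
        assert "range" in rec["hyperparameters"]


class TestMcmcDeterminism:
    def test_fixed_seed_identical_chains(self, iid_data):
        spec = sp.ModelSpec(covariates=["som"], include_spatial=False,
                            include_state=False)
        a = sp.mcmc_oracle(spec, iid_data, iterations=300, seed=4)
        b = sp.mcmc_oracle(spec, iid_data, iterations=300, seed=4)
        np.testing.assert_array_equal(a["beta"], b["beta"])
        np.testing.assert_array_equal(a["theta_log"], b["theta_log"])
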