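"""Model comparison, predictive checks, cross-validation and sensitivity.

WAIC uses the variance-based effective-parameter form, DIC the
posterior-mean plug-in deviance, and LCPO the negative mean log conditional
predictive ordinate — lower is better for all three.  For the conditionally
Gaussian (lognormal) family, CPO and leave-out predictive densities are
computed exactly per hyperparameter grid point by Gaussian conditioning
(a Woodbury downdate of the observation covariance), mixed with the
standard inverse-weighting identity; the gamma family falls back to
importance weighting over posterior draws with a brute-force refit when
any weight dominates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import logsumexp
from scipy.stats import norm

from .mesh import Mesh, build_mesh, coarse_mesh_params, fine_mesh_params
from .spde_model import ModelFit, ModelSpec, fit as fit_model

logger = logging.getLogger(__name__)

__all__ = [
    "CriteriaReport",
    "PpcSummary",
    "waic",
    "dic",
    "cpo",
    "lcpo",
    "fit_model_list",
    "posterior_predictive_check",
    "plot_ppc",
    "cross_validate",
    "sensitivity_suite",
]

_N_DRAWS = 1000


# ---------------------------------------------------------------------------
# information criteria


def waic(fit: ModelFit, n_draws: int = _N_DRAWS, seed: int | None = None) -> float:
    """WAIC = -2 sum_i [log E p(y_i | draw) - Var log p(y_i | draw)]."""
    L = fit.pointwise_loglik(n_draws, seed)
    S = L.shape[0]
    lppd = logsumexp(L, axis=0) - np.log(S)
    p_eff = L.var(axis=0, ddof=1)
    bad = np.where(~np.isfinite(lppd))[0]
    if bad.size:
        logger.warning("waic: degenerate predictive density at obs %s", bad.tolist())
    return float(-2.0 * np.sum(lppd - p_eff))


def dic(fit: ModelFit, n_draws: int = _N_DRAWS, seed: int | None = None) -> float:
    """DIC = posterior-mean deviance + effective parameters (plug-in form)."""
    L = fit.pointwise_loglik(n_draws, seed)
    d_bar = float(np.mean(-2.0 * L.sum(axis=1)))
    eta_hat = fit.asm.A @ fit.latent_mean()
    d_hat = float(-2.0 * fit.asm.loglik(eta_hat, fit.hyper_mean()).sum())
    p_d = d_bar - d_hat
    return d_bar + p_d


def _gaussian_obs_precision(fit: ModelFit, g: int) -> tuple[np.ndarray, np.ndarray]:
    """(Lambda, z_c) for grid point g: precision of the marginal Gaussian of
    the log-responses, via Lambda = D - D A H^-1 A' D, and the centred data."""
    asm = fit.asm
    cond = fit.conditionals[g]
    D = cond.D
    DA = sp.diags(D) @ asm.A
    V = cond.factor().solve(np.asarray(DA.T.todense()))
    cond.release()
    Lam = np.diag(D) - np.asarray(DA @ V)
    z_c = np.log(asm.y) - asm.A @ asm.mu0
    return Lam, z_c


def _exact_loo_densities(fit: ModelFit, groups: list[np.ndarray]) -> np.ndarray:
    """(g_grid, n_groups-worth) leave-out predictive densities of y_i for the
    lognormal family.  ``groups[i]`` is the index set removed when predicting
    observation i (itself alone for LOO, its neighbor ball for LGO)."""
    n = fit.n_obs
    out = np.empty((len(fit.conditionals), n))
    y = fit.asm.y
    for g in range(len(fit.conditionals)):
        Lam, z_c = _gaussian_obs_precision(fit, g)
        Lz = Lam @ z_c
        for i, G in enumerate(groups):
            if len(G) == 1:
                var = 1.0 / Lam[i, i]
                mean = z_c[i] - Lz[i] * var
            else:
                sub = np.ix_(G, G)
                cov_G = np.linalg.inv(Lam[sub])
                delta = cov_G @ Lz[G]
                pos = int(np.where(G == i)[0][0])
                mean = z_c[i] - delta[pos]
                var = cov_G[pos, pos]
            # density of y_i (lognormal change of variables)
            out[g, i] = norm.pdf(np.log(y[i]), mean, np.sqrt(var)) / y[i]
    return out


def cpo(
    fit: ModelFit,
    n_draws: int = _N_DRAWS,
    seed: int | None = None,
    refit_threshold: float = 0.2,
) -> np.ndarray:
    """Conditional predictive ordinate of each observation.

    Lognormal family: exact Gaussian conditioning mixed over the
    hyperparameter grid with 1/CPO_i = sum_g w_g / p_g(y_i | y_-i).
    Gamma family: harmonic-mean importance weighting over posterior draws,
    refitting without the observation whenever one weight carries more than
    ``refit_threshold`` of the total.
    """
    if fit.spec.family == "lognormal":
        groups = [np.array([i]) for i in range(fit.n_obs)]
        dens = _exact_loo_densities(fit, groups)
        inv = fit.grid_weights @ (1.0 / dens)
        return 1.0 / inv
    L = fit.pointwise_loglik(n_draws, seed)
    S = L.shape[0]
    out = np.empty(fit.n_obs)
    for i in range(fit.n_obs):
        u = np.exp(-(L[:, i] - L[:, i].min()))
        frac = u.max() / u.sum()
        if frac > refit_threshold:
            out[i] = _refit_impl(fit, np.array([i]), i, n_draws, seed)
        else:
            out[i] = np.exp(-(logsumexp(-L[:, i]) - np.log(S)))
    return out


def lcpo(fit: ModelFit, n_draws: int = _N_DRAWS, seed: int | None = None) -> float:
    """Mean negative log CPO; lower indicates better predictive fit."""
    c = cpo(fit, n_draws, seed)
    bad = np.where(~(c > 0))[0]
    if bad.size:
        logger.warning("lcpo: zero predictive density at obs %s", bad.tolist())
    return float(-np.mean(np.log(np.clip(c, 1e-300, None))))


# ---------------------------------------------------------------------------
# automated model fitting


@dataclass
class CriteriaReport:
    """Per-model criteria, ranked ascending by WAIC (ties: LCPO)."""

    table: pd.DataFrame
    fits: dict[str, ModelFit] = dc_field(default_factory=dict)

    @property
    def top_model(self) -> str:
        return str(self.table.iloc[0]["name"])

    @property
    def top_fit(self) -> ModelFit:
        return self.fits[self.top_model]

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def _parse_covariates(cell) -> list[str]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return []
    s = str(cell).strip()
    if not s or s.lower() == "none":
        return []
    for sep in (",", ";"):
        s = s.replace(sep, " ")
    return s.split()


def read_model_list(source: str | Path | pd.DataFrame) -> list[ModelSpec]:
    """Model list from CSV: columns name, family, covariates (comma/space
    separated), include_spatial, include_state."""
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    specs = []
    required = {"name", "family"}
    if not required <= set(df.columns):
        raise ValueError(f"model list must have columns {sorted(required)}")
    for idx, row in df.iterrows():
        try:
            spec = ModelSpec(
                name=str(row["name"]),
                family=str(row["family"]),
                covariates=_parse_covariates(row.get("covariates")),
                include_spatial=bool(row.get("include_spatial", True)),
                include_state=bool(row.get("include_state", True)),
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"malformed model-list row {idx}: {exc}") from exc
        specs.append(spec)
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate model names: {dup}")
    return specs


def fit_model_list(
    source: str | Path | pd.DataFrame,
    data: pd.DataFrame,
    mesh: Mesh | None,
    seed: int = 0,
    n_draws: int = _N_DRAWS,
    compute_lcpo: bool = False,
) -> CriteriaReport:
    """Fit every listed model and rank by WAIC (WAIC prioritized over DIC).

    ``compute_lcpo=False`` skips the (more expensive) LCPO column; the
    ranking tie-break then uses DIC.
    """
    specs = read_model_list(source)
    available = set(data.columns)
    rows, fits = [], {}
    for spec in specs:
        missing = [c for c in spec.covariates if c not in available]
        if missing:
            raise ValueError(f"model {spec.name!r}: unknown covariates {missing}")
        f = fit_model(spec, data, mesh, seed=seed)
        row = {
            "name": spec.name,
            "family": spec.family,
            "covariates": " ".join(spec.covariates),
            "waic": waic(f, n_draws),
            "dic": dic(f, n_draws),
        }
        row["lcpo"] = lcpo(f, n_draws) if compute_lcpo else np.nan
        rows.append(row)
        fits[spec.name] = f
    table = pd.DataFrame(rows)
    tie = "lcpo" if compute_lcpo else "dic"
    table = table.sort_values(["waic", tie], kind="mergesort").reset_index(drop=True)
    table["selected_top"] = [i == 0 for i in range(len(table))]
    return CriteriaReport(table=table, fits=fits)


# ---------------------------------------------------------------------------
# posterior predictive checks


@dataclass
class PpcSummary:
    """Simulated-statistic intervals vs observed values.

    ``table`` has one row per statistic (mean, median, variance, q90) with
    the 95% simulated interval and an inside-interval flag; ``simulated``
    keeps the raw per-replicate statistics.
    """

    table: pd.DataFrame
    simulated: dict[str, np.ndarray]
    n: int


def simulate_replicates(fit: ModelFit, n: int, seed: int | None) -> np.ndarray:
    """(n, n_obs) datasets simulated from the joint posterior predictive."""
    draws = fit.sample_posterior(n, seed)
    eta = np.asarray((fit.asm.A @ draws["latent"].T).T)
    rng = np.random.default_rng((fit.seed if seed is None else seed) + 7919)
    if fit.spec.family == "lognormal":
        s = draws["sigma_obs"][:, None]
        return np.exp(eta + rng.standard_normal(eta.shape) * s)
    shape = draws["shape"][:, None]
    return rng.gamma(shape, np.exp(eta) / shape)


def posterior_predictive_check(
    fit: ModelFit, n: int = 1000, seed: int | None = None
) -> PpcSummary:
    """Compare mean/median/variance/90th-quantile of replicate datasets
    against the observed statistics (95% simulated intervals)."""
    reps = simulate_replicates(fit, n, seed)
    y = fit.asm.y
    stats_fns = {
        "mean": lambda a: a.mean(axis=-1),
        "median": lambda a: np.median(a, axis=-1),
        "variance": lambda a: a.var(axis=-1, ddof=1),
        "q90": lambda a: np.quantile(a, 0.9, axis=-1),
    }
    rows, sims = [], {}
    for name, fn in stats_fns.items():
        sim = np.asarray(fn(reps))
        obs = float(fn(y[None, :])[0])
        lo, hi = np.quantile(sim, [0.025, 0.975])
        rows.append(
            {
                "statistic": name,
                "observed": obs,
                "sim_mean": float(sim.mean()),
                "ci_lower": float(lo),
                "ci_upper": float(hi),
                "inside": bool(lo <= obs <= hi),
            }
        )
        sims[name] = sim
    return PpcSummary(table=pd.DataFrame(rows), simulated=sims, n=n)


def plot_ppc(summary: PpcSummary, path: str | Path, statistics=("mean", "median")) -> None:
    """Side-by-side histograms of simulated statistics with the observed line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(statistics), figsize=(5 * len(statistics), 4))
    axes = np.atleast_1d(axes)
    obs = summary.table.set_index("statistic")["observed"]
    for ax, name in zip(axes, statistics):
        ax.hist(summary.simulated[name], bins=30, color="grey")
        ax.axvline(obs[name], color="red")
        ax.set_title(f"simulated {name}")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


# ---------------------------------------------------------------------------
# cross-validation


def cross_validate(
    fit: ModelFit,
    mode: str = "loo",
    group_size: int = 6,
    seed: int = 0,
    n_draws: int = _N_DRAWS,
    refit_threshold: float = 0.2,
) -> dict:
    """Leave-one-out / leave-group-out expected log predictive densities.

    LGO removes each observation together with its (group_size - 1)
    nearest spatial neighbors and scores the held-out observation.  Exact
    Gaussian conditioning is used for the lognormal family; importance
    weighting (with refit fallback) for the gamma family.  Returns
    per-observation scores and their mean.
    """
    if mode not in ("loo", "lgo"):
        raise ValueError("mode must be 'loo' or 'lgo'")
    n = fit.n_obs
    if mode == "lgo":
        if group_size >= n:
            raise ValueError("group_size must be smaller than n")
        from scipy.spatial import cKDTree

        coords = fit.coords
        tree = cKDTree(coords)
        _, nbrs = tree.query(coords, k=group_size)
        groups = [np.unique(np.atleast_1d(nbrs[i])) for i in range(n)]
        for i in range(n):
            if i not in groups[i]:
                groups[i] = np.append(groups[i], i)
    else:
        groups = [np.array([i]) for i in range(n)]

    if fit.spec.family == "lognormal":
        dens = _exact_loo_densities(fit, groups)
        inv = fit.grid_weights @ (1.0 / dens)
        scores = -np.log(inv)
    else:
        L = fit.pointwise_loglik(n_draws, seed)
        scores = np.empty(n)
        for i, G in enumerate(groups):
            lg = L[:, G].sum(axis=1)
            u = np.exp(-(lg - lg.max()))
            if u.max() / u.sum() > refit_threshold and n <= 400:
                scores[i] = np.log(_refit_impl(fit, G, i, n_draws, seed))
            else:
                # E[1/p]^-1 under draws, scored at the target observation
                w = u / u.sum()
                scores[i] = logsumexp(L[:, i], b=w, axis=0)
    return {
        "mode": mode,
        "group_size": group_size if mode == "lgo" else 1,
        "scores": scores,
        "mean_score": float(scores.mean()),
    }


def _refit_impl(
    fit: ModelFit, group: np.ndarray, target: int, n_draws: int, seed: int | None
) -> float:
    """Refit without ``group`` and average the predictive density at ``target``."""
    asm = fit.asm
    frame = {"conc": asm.y, "x_km": fit.coords[:, 0], "y_km": fit.coords[:, 1]}
    for j, c in enumerate(fit.spec.covariates):
        frame[c] = asm.X[:, j + 1]
    if fit.spec.include_state:
        frame["state_id"] = np.array(fit.state_ids)
    else:
        frame["state_id"] = "s0"
    df = pd.DataFrame(frame)
    keep = np.setdiff1d(np.arange(fit.n_obs), group)
    sub = fit_model(fit.spec, df.iloc[keep].reset_index(drop=True), fit.mesh,
                    seed=fit.seed)
    # predictive density at the held-out location
    from .mesh import projection_matrix

    row_parts = []
    if fit.spec.include_spatial:
        row_parts.append(projection_matrix(fit.mesh, fit.coords[[target]]))
    row_parts.append(sp.csr_matrix(asm.X[[target]]))
    if fit.spec.include_state:
        levels = sub.asm.state_levels
        z = np.zeros((1, len(levels)))
        sid = str(fit.state_ids[target])
        if sid in levels:
            z[0, levels.index(sid)] = 1.0
        row_parts.append(sp.csr_matrix(z))
    A_t = sp.hstack(row_parts).tocsr()
    draws = sub.sample_posterior(n_draws, seed)
    eta_t = np.asarray((A_t @ draws["latent"].T).ravel())
    y_t = asm.y[target]
    dens = np.empty(len(eta_t))
    yy = sub.asm.y
    for s_i, (e, p) in enumerate(zip(eta_t, draws["params"])):
        sub.asm.y = np.array([y_t])
        dens[s_i] = np.exp(sub.asm.loglik(np.array([e]), p))[0]
    sub.asm.y = yy
    return float(dens.mean())


# ---------------------------------------------------------------------------
# sensitivity


def sensitivity_suite(
    spec: ModelSpec,
    data: pd.DataFrame,
    variants: list[dict],
    boundary,
    range_estimate: float,
    baseline_fraction: float = 1.0 / 10.0,
    seed: int = 0,
    n_draws: int = _N_DRAWS,
) -> pd.DataFrame:
    """Refit the model under mesh/cutoff/prior variants and tabulate.

    Each variant is a dict with any of the keys ``mesh_fraction``,
    ``cutoff``, ``range_prior``, ``sigma_prior``, ``intercept_prior``,
    ``fixed_prior`` (unknown keys are an error).  The output flags variants
    whose WAIC departs from the baseline by more than 10 units; smaller
    differences are treated as equivalent fits.
    """
    allowed = {
        "mesh_fraction", "cutoff", "range_prior", "sigma_prior",
        "intercept_prior", "fixed_prior", "label",
    }
    for v in variants:
        unknown = set(v) - allowed
        if unknown:
            raise ValueError(f"unknown variant key(s): {sorted(unknown)}")

    pts = data[["x_km", "y_km"]].to_numpy(float)
    coarse = coarse_mesh_params(pts)

    def one(label: str, variant: dict) -> dict:
        frac = variant.get("mesh_fraction", baseline_fraction)
        cut = variant.get("cutoff")
        params = fine_mesh_params(range_estimate, coarse, frac, cutoff_override=cut)
        m = build_mesh(pts, boundary, params)
        s = ModelSpec(
            **{
                **spec.__dict__,
                "name": label,
                "range_prior": variant.get("range_prior", spec.range_prior),
                "sigma_prior": variant.get("sigma_prior", spec.sigma_prior),
                "intercept_prior": variant.get("intercept_prior", spec.intercept_prior),
                "fixed_prior": variant.get("fixed_prior", spec.fixed_prior),
            }
        )
        f = fit_model(s, data, m, seed=seed)
        hyper = f.hyper_mean()
        row = {
            "label": label,
            "mesh_fraction": frac,
            "cutoff": cut if cut is not None else params.cutoff,
            "n_nodes": m.n_nodes,
            "waic": waic(f, n_draws),
            "dic": dic(f, n_draws),
            "range_mean": hyper.get("range", np.nan),
            "sigma_mean": hyper.get("sigma", np.nan),
        }
        for nm, b in zip(f.effect_names, f.beta_mean()):
            row[f"beta_{nm}"] = b
        return row

    rows = [one("baseline", {})]
    for i, v in enumerate(variants):
        rows.append(one(v.get("label", f"variant{i}"), v))
    out = pd.DataFrame(rows)
    out["delta_waic"] = out["waic"] - out.loc[0, "waic"]
    out["waic_equivalent"] = out["delta_waic"].abs() < 10.0
    return out
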