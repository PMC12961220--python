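"""Hierarchical SPDE spatial model: priors, likelihoods and inference.

The latent field w(s) is a Matern (nu = 1) Gaussian random field represented
as a Gaussian Markov random field on the mesh through the SPDE finite-element
construction: with kappa = sqrt(8)/range and tau^2 = 1 / (4 pi kappa^2
sigma^2), the node precision is

    Q(range, sigma) = tau^2 (kappa^4 C + 2 kappa^2 G + G C^-1 G)
                    = tau^2 M^T C^-1 M,      M = kappa^2 C + G,

with C the (lumped) mass matrix and G the stiffness matrix.  The observation
model on the log-concentration scale is

    eta = beta0 + X beta + A w + u_state,

with iid state effects u and either a Gaussian log-response (lognormal
family) or a gamma response with mean exp(eta) and shape phi.

Inference integrates the hyperparameters over a deterministic grid centred
on the posterior mode (found by numerical optimization, with a
finite-difference Hessian setting the grid scale); conditional on the
hyperparameters the latent vector is exactly Gaussian (lognormal family) or
Laplace-approximated by an inner Newton iteration (gamma family).  Posterior
draws use Matheron's rule so only sparse solves are needed.  A
Metropolis-within-Gibbs sampler over the same model provides an independent
inference oracle for tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .mesh import Mesh, projection_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "SpdeOperator",
    "PcPrior",
    "ModelSpec",
    "ModelFit",
    "assemble_fem",
    "pc_prior",
    "default_range_threshold",
    "fit",
    "sample_posterior",
    "mcmc_oracle",
]

# latent dimension above which factorizations switch from dense Cholesky
# to SuperLU; both paths are exact
_DENSE_LIMIT = 700


# ---------------------------------------------------------------------------
# finite elements


@dataclass
class SpdeOperator:
    """FEM matrices and the Matern precision map for one mesh."""

    C_diag: np.ndarray       # lumped mass matrix diagonal
    G: sp.csr_matrix         # stiffness matrix
    GCG: sp.csr_matrix       # G C^-1 G, precomputed
    mesh: Mesh

    @property
    def n_nodes(self) -> int:
        return self.C_diag.shape[0]

    @staticmethod
    def kappa(range_: float) -> float:
        return math.sqrt(8.0) / range_

    @staticmethod
    def tau(range_: float, sigma: float) -> float:
        k = SpdeOperator.kappa(range_)
        return 1.0 / math.sqrt(4.0 * math.pi * k**2 * sigma**2)

    def M_matrix(self, range_: float) -> sp.csr_matrix:
        """kappa^2 C + G — the symmetric 'half' of the precision."""
        k2 = self.kappa(range_) ** 2
        return (sp.diags(k2 * self.C_diag) + self.G).tocsr()

    def precision(self, range_: float, sigma: float) -> sp.csr_matrix:
        if range_ <= 0 or sigma <= 0:
            raise ValueError("range and sigma must be positive")
        k = self.kappa(range_)
        t2 = self.tau(range_, sigma) ** 2
        Q = t2 * (
            sp.diags(k**4 * self.C_diag) + 2.0 * k**2 * self.G + self.GCG
        )
        return Q.tocsr()

    def _pencil_eigs(self) -> np.ndarray | None:
        """Eigenvalues of C^-1/2 G C^-1/2, cached; None for large meshes."""
        if not hasattr(self, "_eigs"):
            if self.n_nodes <= 1500:
                s = 1.0 / np.sqrt(self.C_diag)
                K = (sp.diags(s) @ self.G @ sp.diags(s)).toarray()
                self._eigs = np.linalg.eigvalsh(0.5 * (K + K.T))
            else:
                self._eigs = None
        return self._eigs

    def logdet_precision(self, range_: float, sigma: float) -> float:
        """log det Q = 2m log tau + log det C + 2 sum log(kappa^2 + gamma_i),
        using the cached eigenvalues of the (C, G) pencil; falls back to a
        factorization of M = kappa^2 C + G on large meshes."""
        m = self.n_nodes
        t = self.tau(range_, sigma)
        k2 = self.kappa(range_) ** 2
        eigs = self._pencil_eigs()
        if eigs is not None:
            return (
                2.0 * m * math.log(t)
                + float(np.log(self.C_diag).sum())
                + 2.0 * float(np.log(k2 + np.clip(eigs, 0.0, None)).sum())
            )
        f = _Factor(self.M_matrix(range_))
        return 2.0 * m * math.log(t) + 2.0 * f.logdet() - np.log(self.C_diag).sum()


def assemble_fem(mesh: Mesh) -> SpdeOperator:
    """Assemble P1 mass (lumped) and stiffness matrices over all triangles."""
    pts = mesh.nodes
    tris = mesh.triangles
    p = pts[tris]
    # signed double areas
    det = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
        p[:, 2, 0] - p[:, 0, 0]
    ) * (p[:, 1, 1] - p[:, 0, 1])
    areas = 0.5 * np.abs(det)
    bad = np.where(areas <= 1e-14)[0]
    if bad.size:
        raise ValueError(f"degenerate triangle(s) at index {bad.tolist()}")

    # basis gradients: b_i = (y_j - y_k, x_k - x_j) / (2A), (i,j,k) cyclic
    n = pts.shape[0]
    C_diag = np.zeros(n)
    np.add.at(C_diag, tris.ravel(), np.repeat(areas / 3.0, 3))

    grads = np.empty((tris.shape[0], 3, 2))
    for i in range(3):
        j, k = (i + 1) % 3, (i + 2) % 3
        grads[:, i, 0] = p[:, j, 1] - p[:, k, 1]
        grads[:, i, 1] = p[:, k, 0] - p[:, j, 0]
    grads /= (2.0 * areas)[:, None, None]

    rows, cols, vals = [], [], []
    for i in range(3):
        for j in range(3):
            rows.append(tris[:, i])
            cols.append(tris[:, j])
            vals.append(areas * np.einsum("td,td->t", grads[:, i], grads[:, j]))
    G = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    G.sum_duplicates()
    GCG = (G @ sp.diags(1.0 / C_diag) @ G).tocsr()
    return SpdeOperator(C_diag=C_diag, G=G, GCG=GCG, mesh=mesh)


# ---------------------------------------------------------------------------
# priors


@dataclass(frozen=True)
class PcPrior:
    """Penalized-complexity prior calibrated by a tail statement.

    kind="sigma" (also used for the observation SD): exponential with rate
    lambda = -ln(alpha)/u so that P(sigma > u) = alpha.
    kind="range" (2-D field): density lambda p^-2 exp(-lambda/p) with
    lambda = -u ln(alpha) so that P(p < u) = alpha.
    """

    kind: str
    u: float
    alpha: float

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie strictly in (0, 1)")
        if self.u <= 0:
            raise ValueError("threshold u must be positive")
        if self.kind not in ("range", "sigma"):
            raise ValueError(f"unknown PC prior kind {self.kind!r}")

    @property
    def lam(self) -> float:
        if self.kind == "sigma":
            return -math.log(self.alpha) / self.u
        return -self.u * math.log(self.alpha)

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        lam = self.lam
        if self.kind == "sigma":
            return np.where(x >= 0, math.log(lam) - lam * x, -np.inf)
        return np.where(x > 0, math.log(lam) - 2.0 * np.log(x) - lam / x, -np.inf)

    def pdf(self, x: np.ndarray) -> np.ndarray:
        return np.exp(self.logpdf(x))

    def cdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        lam = self.lam
        if self.kind == "sigma":
            return np.where(x > 0, 1.0 - np.exp(-lam * x), 0.0)
        with np.errstate(divide="ignore"):
            return np.where(x > 0, np.exp(-lam / x), 0.0)

    def quantile(self, q: np.ndarray) -> np.ndarray:
        q = np.asarray(q, float)
        lam = self.lam
        if self.kind == "sigma":
            return -np.log1p(-q) / lam
        return -lam / np.log(q)

    def sample(self, n: int, seed: int = 0) -> np.ndarray:
        rng = np.random.default_rng(seed)
        return self.quantile(rng.uniform(size=n))


def pc_prior(kind: str, u: float, alpha: float) -> PcPrior:
    """Construct a PC prior from its tail statement (u, alpha)."""
    return PcPrior(kind=kind, u=u, alpha=alpha)


def default_range_threshold(points: np.ndarray) -> float:
    """range_ob: half the x-extent of the point set."""
    points = np.atleast_2d(np.asarray(points, float))
    if points.shape[0] < 2:
        raise ValueError("need at least 2 points")
    extent = float(points[:, 0].max() - points[:, 0].min())
    if extent <= 0:
        raise ValueError("zero x-extent")
    return extent / 2.0


# ---------------------------------------------------------------------------
# model specification


@dataclass
class ModelSpec:
    """One candidate model: family, covariates, effect flags and priors.

    Priors are given as tuples: fixed-effect/intercept priors as
    (mean, precision) Gaussians; PC priors as (u, alpha); the state-effect
    precision prior and gamma-shape prior as (shape, rate) gammas.  The
    default fixed-effect precision 1e-4 is the weakly-informative baseline.
    ``range_prior=None`` defers to range_ob (half the data x-extent).
    ``fixed_hyper`` pins named hyperparameters ("range", "sigma",
    "sigma_obs", "shape", "tau_state") at fixed values instead of
    integrating them.
    """

    name: str = "model"
    family: str = "lognormal"
    covariates: list[str] = dc_field(default_factory=list)
    include_spatial: bool = True
    include_state: bool = True
    intercept_prior: tuple[float, float] = (0.0, 1e-4)
    fixed_prior: tuple[float, float] = (0.0, 1e-4)
    range_prior: tuple[float, float] | None = None
    sigma_prior: tuple[float, float] = (0.5, 0.5)
    state_prec_prior: tuple[float, float] = (1.0, 5e-5)
    obs_sd_prior: tuple[float, float] = (1.0, 0.1)
    gamma_shape_prior: tuple[float, float] = (1.0, 0.1)
    fixed_hyper: dict = dc_field(default_factory=dict)
    grid_points: int | None = None
    grid_halfwidth: float = 3.0

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "gamma"):
            raise ValueError(f"unsupported family: {self.family!r}")


# ---------------------------------------------------------------------------
# linear algebra helpers


class _Factor:
    """Symmetric positive-definite factorization with a dense/sparse switch."""

    def __init__(self, Q, dense_limit: int = _DENSE_LIMIT):
        n = Q.shape[0]
        self.n = n
        if sp.issparse(Q) and n > dense_limit:
            self._lu = spla.splu(
                Q.tocsc(),
                permc_spec="MMD_AT_PLUS_A",
                diag_pivot_thresh=0.0,
                options={"SymmetricMode": True},
            )
            self._dense = None
        else:
            A = Q.toarray() if sp.issparse(Q) else np.asarray(Q)
            self._dense = cho_factor(A, lower=True)
            self._lu = None

    def solve(self, b: np.ndarray) -> np.ndarray:
        if self._dense is not None:
            return cho_solve(self._dense, b)
        if b.ndim == 1:
            return self._lu.solve(b)
        return np.column_stack([self._lu.solve(b[:, j]) for j in range(b.shape[1])])

    def logdet(self) -> float:
        if self._dense is not None:
            return 2.0 * float(np.log(np.diag(self._dense[0])).sum())
        return float(np.log(np.abs(self._lu.U.diagonal())).sum())


# ---------------------------------------------------------------------------
# model assembly


class _Assembled:
    """Design matrices, latent layout and prior pieces for one model/data."""

    def __init__(self, spec: ModelSpec, data: pd.DataFrame, mesh: Mesh | None):
        self.spec = spec
        y = data["conc"].to_numpy(float)
        if np.any(~np.isfinite(y)) or np.any(y <= 0):
            raise ValueError("responses must be positive and finite")
        self.y = y
        n = len(y)

        X_cols = [np.ones(n)]
        for c in spec.covariates:
            X_cols.append(data[c].to_numpy(float))
        X = np.column_stack(X_cols)
        r = np.linalg.matrix_rank(X)
        if r < X.shape[1]:
            # name the columns loading on the null space
            _, _, vt = np.linalg.svd(X, full_matrices=False)
            load = np.abs(vt[r:]).max(axis=0)
            aliased = [
                (["intercept"] + spec.covariates)[i]
                for i in np.argsort(load)[::-1][: X.shape[1] - r]
            ]
            raise ValueError(f"singular design; aliased columns: {aliased}")
        self.X = X
        self.p = X.shape[1]

        self.mesh = mesh
        self.operator = None
        self.m = 0
        if {"x_km", "y_km"} <= set(data.columns):
            self.coords = data[["x_km", "y_km"]].to_numpy(float)
        else:
            self.coords = np.zeros((n, 2))
        self.state_ids = (
            data["state_id"].astype(str).tolist()
            if "state_id" in data.columns
            else ["s0"] * n
        )
        blocks = []
        if spec.include_spatial:
            if mesh is None:
                raise ValueError("spatial model requires a mesh")
            self.operator = assemble_fem(mesh)
            self.m = self.operator.n_nodes
            pts = data[["x_km", "y_km"]].to_numpy(float)
            self.A_proj = projection_matrix(mesh, pts)
            blocks.append(self.A_proj)
        blocks.append(sp.csr_matrix(X))
        if spec.include_state:
            levels = sorted(data["state_id"].astype(str).unique())
            self.state_levels = levels
            idx = {s: i for i, s in enumerate(levels)}
            cols = np.array([idx[s] for s in data["state_id"].astype(str)])
            Z = sp.csr_matrix(
                (np.ones(n), (np.arange(n), cols)), shape=(n, len(levels))
            )
            self.s = len(levels)
            blocks.append(Z)
        else:
            self.state_levels = []
            self.s = 0
        self.A = sp.hstack(blocks).tocsr()
        self.AtA = (self.A.T @ self.A).tocsr()
        self.dim = self.m + self.p + self.s
        self.sl_w = slice(0, self.m)
        self.sl_beta = slice(self.m, self.m + self.p)
        self.sl_u = slice(self.m + self.p, self.dim)

        # fixed-effect prior
        self.beta_prec = np.array(
            [spec.intercept_prior[1]] + [spec.fixed_prior[1]] * (self.p - 1)
        )
        self.mu0 = np.zeros(self.dim)
        self.mu0[self.sl_beta] = np.array(
            [spec.intercept_prior[0]] + [spec.fixed_prior[0]] * (self.p - 1)
        )

        # hyperparameter layout
        names = []
        if spec.include_spatial:
            names += ["range", "sigma"]
        names.append("sigma_obs" if spec.family == "lognormal" else "shape")
        if spec.include_state:
            names.append("tau_state")
        self.hyper_names = [nm for nm in names if nm not in spec.fixed_hyper]
        self.fixed_hyper = dict(spec.fixed_hyper)

        if spec.include_spatial:
            if spec.range_prior is None:
                u_range = default_range_threshold(data[["x_km", "y_km"]].to_numpy())
                alpha_range = 0.5
            else:
                u_range, alpha_range = spec.range_prior
            self.range_prior = PcPrior("range", u_range, alpha_range)
            self.sigma_prior = PcPrior("sigma", *spec.sigma_prior)
        self.obs_sd_prior = PcPrior("sigma", *spec.obs_sd_prior)

    # -- hyperparameter handling ------------------------------------------

    def theta_to_params(self, theta: np.ndarray) -> dict[str, float]:
        params = dict(self.fixed_hyper)
        for nm, t in zip(self.hyper_names, theta):
            params[nm] = math.exp(t)
        return params

    def log_hyper_prior(self, theta: np.ndarray) -> float:
        """Prior density in theta = log(param) space (Jacobian included)."""
        params = self.theta_to_params(theta)
        lp = 0.0
        for nm in self.hyper_names:
            v = params[nm]
            if nm == "range":
                lp += float(self.range_prior.logpdf(v))
            elif nm == "sigma":
                lp += float(self.sigma_prior.logpdf(v))
            elif nm == "sigma_obs":
                lp += float(self.obs_sd_prior.logpdf(v))
            elif nm == "shape":
                a, r = self.spec.gamma_shape_prior
                lp += float(stats.gamma.logpdf(v, a, scale=1.0 / r))
            elif nm == "tau_state":
                a, r = self.spec.state_prec_prior
                lp += float(stats.gamma.logpdf(v, a, scale=1.0 / r))
            lp += math.log(v)  # Jacobian d(param)/d(log param)
        return lp

    def initial_theta(self) -> np.ndarray:
        log_y = np.log(self.y)
        resid_sd = float(np.std(log_y - self.X @ np.linalg.lstsq(self.X, log_y, rcond=None)[0]))
        init = {
            "range": self.range_prior.u if self.spec.include_spatial else 1.0,
            "sigma": max(self.sigma_prior.u, 0.1) if self.spec.include_spatial else 1.0,
            "sigma_obs": max(0.7 * resid_sd, 0.05),
            "shape": max(1.0 / max(resid_sd**2, 1e-3), 0.5),
            "tau_state": 25.0,
        }
        return np.array([math.log(init[nm]) for nm in self.hyper_names])

    # -- prior precision --------------------------------------------------

    def prior_precision(self, params: dict[str, float]) -> sp.csr_matrix:
        blocks = []
        if self.spec.include_spatial:
            blocks.append(self.operator.precision(params["range"], params["sigma"]))
        blocks.append(sp.diags(self.beta_prec))
        if self.spec.include_state:
            blocks.append(params["tau_state"] * sp.eye(self.s))
        return sp.block_diag(blocks, format="csr")

    def logdet_prior(self, params: dict[str, float]) -> float:
        ld = float(np.log(self.beta_prec).sum())
        if self.spec.include_spatial:
            ld += self.operator.logdet_precision(params["range"], params["sigma"])
        if self.spec.include_state:
            ld += self.s * math.log(params["tau_state"])
        return ld

    # -- observation model ------------------------------------------------

    def loglik(self, eta: np.ndarray, params: dict[str, float]) -> np.ndarray:
        """Pointwise log density of the observed concentrations."""
        if self.spec.family == "lognormal":
            s = params["sigma_obs"]
            z = np.log(self.y)
            return stats.norm.logpdf(z, eta, s) - z  # Jacobian of y -> log y
        phi = params["shape"]
        return (
            phi * (math.log(phi) - eta)
            + (phi - 1.0) * np.log(self.y)
            - phi * self.y * np.exp(-eta)
            - math.lgamma(phi)
        )


# ---------------------------------------------------------------------------
# conditional (given hyperparameters) computations


class _Conditional:
    """Latent conditional N(mu, H^-1) at one hyperparameter configuration.

    H = Q_prior + A' D A with diagonal working precision D (1/sigma_obs^2
    for the Gaussian log-response; the Newton weights at the mode for the
    gamma family).
    """

    def __init__(self, asm, params, mu, D, log_marginal):
        self.asm = asm
        self.params = params
        self.mu = mu
        self.D = D
        self.log_marginal = log_marginal
        self._factor = None
        self._Mfac = None

    def factor(self) -> _Factor:
        # factorizations are rebuilt on demand and freed by callers: keeping
        # one per grid point alive would dominate memory on fine meshes
        if self._factor is None:
            Q = self.asm.prior_precision(self.params)
            H = Q + (self.asm.A.T @ sp.diags(self.D) @ self.asm.A)
            self._factor = _Factor(H)
        return self._factor

    def release(self) -> None:
        self._factor = None
        self._Mfac = None

    def sample(self, n: int, rng) -> np.ndarray:
        """Matheron-rule joint draws: prior draw + kriging correction."""
        asm = self.asm
        fac = self.factor()
        # prior draws (columns = draws)
        xp = np.zeros((asm.dim, n))
        if asm.spec.include_spatial:
            op = asm.operator
            if self._Mfac is None:
                self._Mfac = _Factor(op.M_matrix(self.params["range"]))
            t = op.tau(self.params["range"], self.params["sigma"])
            z = np.sqrt(op.C_diag)[:, None] * rng.standard_normal((asm.m, n))
            xp[asm.sl_w] = self._Mfac.solve(z) / t
        xp[asm.sl_beta] = rng.standard_normal((asm.p, n)) / np.sqrt(asm.beta_prec)[:, None]
        if asm.spec.include_state:
            xp[asm.sl_u] = rng.standard_normal((asm.s, n)) / math.sqrt(
                self.params["tau_state"]
            )
        ep = rng.standard_normal((len(asm.y), n)) / np.sqrt(self.D)[:, None]
        resid = -(asm.A @ xp) - ep
        out = self.mu[:, None] + xp + fac.solve(asm.A.T @ (self.D[:, None] * resid))
        return out.T


def _gaussian_conditional(asm: _Assembled, params: dict[str, float]) -> _Conditional:
    """Exact conditional and marginal likelihood for the lognormal family."""
    s2 = params["sigma_obs"] ** 2
    z = np.log(asm.y) - asm.A @ asm.mu0
    D = np.full(len(asm.y), 1.0 / s2)
    Q = asm.prior_precision(params)
    H = Q + asm.AtA / s2
    fac = _Factor(H)
    b = asm.A.T @ (z / s2)
    mu_c = fac.solve(b)
    n = len(asm.y)
    quad = float(z @ z) / s2 - float(b @ mu_c)
    log_marg = (
        -0.5 * n * math.log(2.0 * math.pi * s2)
        + 0.5 * asm.logdet_prior(params)
        - 0.5 * fac.logdet()
        - 0.5 * quad
        - float(np.log(asm.y).sum())  # density of y, not log y
    )
    return _Conditional(asm, params, asm.mu0 + mu_c, D, log_marg)


def _gamma_conditional(
    asm: _Assembled, params: dict[str, float], x_init: np.ndarray | None = None
) -> _Conditional:
    """Inner Newton/Laplace approximation for the gamma family."""
    phi = params["shape"]
    y = asm.y
    Q = asm.prior_precision(params)
    x = np.zeros(asm.dim) if x_init is None else x_init.copy()
    x[asm.sl_beta][0] = x[asm.sl_beta][0] or float(np.log(y.mean()))

    def objective(xv):
        eta = asm.A @ xv
        d = xv - asm.mu0
        return -asm.loglik(eta, params).sum() + 0.5 * float(d @ (Q @ d))

    f_old = objective(x)
    fac = None
    for _ in range(60):
        eta = asm.A @ x
        eta = np.clip(eta, -30, 30)
        w = phi * y * np.exp(-eta)
        grad_ll = -phi + w  # d loglik / d eta
        W = np.clip(w, 1e-10, 1e10)
        H = Q + (asm.A.T @ sp.diags(W) @ asm.A)
        fac = _Factor(H)
        grad = Q @ (x - asm.mu0) - asm.A.T @ grad_ll
        step = fac.solve(grad)
        t = 1.0
        for _ls in range(30):
            x_new = x - t * step
            f_new = objective(x_new)
            if f_new <= f_old + 1e-12:
                break
            t *= 0.5
        if not np.isfinite(f_new):
            raise FloatingPointError("gamma Newton iteration diverged")
        converged = abs(f_old - f_new) < 1e-9 * (1.0 + abs(f_old))
        x, f_old = x_new, f_new
        if converged:
            break

    eta = asm.A @ x
    W = np.clip(phi * y * np.exp(np.clip(-eta, -30, 30)), 1e-10, 1e10)
    H = Q + (asm.A.T @ sp.diags(W) @ asm.A)
    fac = _Factor(H)
    d = x - asm.mu0
    log_marg = (
        asm.loglik(eta, params).sum()
        - 0.5 * float(d @ (Q @ d))
        + 0.5 * asm.logdet_prior(params)
        - 0.5 * fac.logdet()
    )
    return _Conditional(asm, params, x, W, log_marg)


def _conditional(asm, params, x_init=None) -> _Conditional:
    if asm.spec.family == "lognormal":
        return _gaussian_conditional(asm, params)
    return _gamma_conditional(asm, params, x_init)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class ModelFit:
    """Posterior summaries, grid mixture and draw access for one model."""

    spec: ModelSpec
    asm: _Assembled
    mesh: Mesh | None
    hyper_names: list[str]
    theta_mode: np.ndarray
    grid_thetas: np.ndarray        # (g, d)
    grid_weights: np.ndarray       # (g,)
    conditionals: list[_Conditional]
    seed: int
    _draw_cache: dict = dc_field(default_factory=dict)

    # -- basic access ------------------------------------------------------

    @property
    def n_obs(self) -> int:
        return len(self.asm.y)

    @property
    def effect_names(self) -> list[str]:
        return ["intercept"] + list(self.spec.covariates)

    @property
    def coords(self) -> np.ndarray:
        return self.asm.coords

    @property
    def state_ids(self) -> list[str]:
        return self.asm.state_ids

    def latent_mean(self) -> np.ndarray:
        return np.einsum(
            "g,gd->d",
            self.grid_weights,
            np.array([c.mu for c in self.conditionals]),
        )

    def beta_mean(self) -> np.ndarray:
        return self.latent_mean()[self.asm.sl_beta]

    def field_mean(self) -> np.ndarray:
        return self.latent_mean()[self.asm.sl_w]

    def state_effect_mean(self) -> np.ndarray:
        return self.latent_mean()[self.asm.sl_u]

    def hyper_mean(self) -> dict[str, float]:
        out = dict(self.asm.fixed_hyper)
        nat = np.exp(self.grid_thetas)
        for j, nm in enumerate(self.hyper_names):
            out[nm] = float(self.grid_weights @ nat[:, j])
        return out

    def log_marginal_likelihood(self) -> float:
        """Grid-maximum approximation to the evidence (mode height)."""
        lm = np.array([c.log_marginal for c in self.conditionals])
        return float(lm.max())

    def summary(self, n_draws: int = 1000, seed: int | None = None) -> dict:
        """Posterior summary: fixed effects (mean, sd, 95% CI) and
        hyperparameter means."""
        draws = self.sample_posterior(n_draws, seed)["beta"]
        ci = np.quantile(draws, [0.025, 0.975], axis=0)
        return {
            "model": self.spec.name,
            "family": self.spec.family,
            "n_obs": self.n_obs,
            "fixed_effects": {
                nm: {
                    "mean": float(m),
                    "sd": float(s),
                    "ci_lower": float(lo),
                    "ci_upper": float(hi),
                }
                for nm, m, s, lo, hi in zip(
                    self.effect_names, self.beta_mean(),
                    draws.std(axis=0), ci[0], ci[1],
                )
            },
            "hyperparameters": {k: float(v) for k, v in self.hyper_mean().items()},
        }

    def summary_to_json(self, path, n_draws: int = 1000,
                        seed: int | None = None) -> None:
        import json
        from pathlib import Path as _P

        _P(path).write_text(json.dumps(self.summary(n_draws, seed), indent=2))

    # -- draws -------------------------------------------------------------

    def sample_posterior(self, n: int = 1000, seed: int | None = None) -> dict:
        """Joint draws of (latent, hyperparameters) from the grid mixture."""
        if n <= 0:
            raise ValueError("n must be positive")
        seed = self.seed + 1 if seed is None else seed
        key = (n, seed)
        if key in self._draw_cache:
            return self._draw_cache[key]
        rng = np.random.default_rng(seed)
        g_idx = rng.choice(len(self.grid_weights), size=n, p=self.grid_weights)
        latent = np.empty((n, self.asm.dim))
        params_rows = []
        for g in np.unique(g_idx):
            sel = np.where(g_idx == g)[0]
            cond = self.conditionals[g]
            latent[sel] = cond.sample(len(sel), rng)
            cond.release()
        for i in range(n):
            params_rows.append(self.conditionals[g_idx[i]].params)
        draws = {
            "latent": latent,
            "beta": latent[:, self.asm.sl_beta],
            "field": latent[:, self.asm.sl_w],
            "state": latent[:, self.asm.sl_u],
            "params": params_rows,
            "grid_index": g_idx,
        }
        for nm in set(self.hyper_names) | set(self.asm.fixed_hyper):
            draws[nm] = np.array([p[nm] for p in params_rows])
        self._draw_cache.clear()
        self._draw_cache[key] = draws
        return draws

    def beta_interval(
        self, n: int = 1000, level: float = 0.95, seed: int | None = None
    ) -> np.ndarray:
        """(p, 2) credible bounds for intercept + fixed effects from draws."""
        d = self.sample_posterior(n, seed)["beta"]
        a = (1.0 - level) / 2.0
        return np.quantile(d, [a, 1.0 - a], axis=0).T

    def pointwise_loglik(
        self, n: int = 1000, seed: int | None = None
    ) -> np.ndarray:
        """(n_draws, n_obs) matrix of pointwise log predictive densities."""
        draws = self.sample_posterior(n, seed)
        eta = np.asarray((self.asm.A @ draws["latent"].T).T)  # (S, n_obs)
        y = self.asm.y
        if self.spec.family == "lognormal":
            s = draws["sigma_obs"][:, None]
            z = np.log(y)[None, :]
            return stats.norm.logpdf(z, eta, s) - z
        from scipy.special import gammaln

        phi = draws["shape"][:, None]
        return (
            phi * (np.log(phi) - eta)
            + (phi - 1.0) * np.log(y)[None, :]
            - phi * y[None, :] * np.exp(-eta)
            - gammaln(phi)
        )

    def linear_predictor_draws(
        self, n: int = 1000, seed: int | None = None
    ) -> np.ndarray:
        draws = self.sample_posterior(n, seed)
        return np.asarray((self.asm.A @ draws["latent"].T).T)


def _hyper_posterior_builder(asm: _Assembled):
    cache = {"x": None}

    def log_post(theta: np.ndarray) -> float:
        params = asm.theta_to_params(theta)
        try:
            cond = _conditional(asm, params, cache["x"])
        except (FloatingPointError, np.linalg.LinAlgError):
            return -np.inf
        if asm.spec.family == "gamma":
            cache["x"] = cond.mu
        return cond.log_marginal + asm.log_hyper_prior(theta)

    return log_post


def fit(
    spec: ModelSpec,
    data: pd.DataFrame,
    mesh: Mesh | None = None,
    seed: int = 0,
) -> ModelFit:
    """Fit one hierarchical model by hyperparameter-grid integration.

    The hyperparameter posterior mode is located by numerical optimization
    of the (exact or Laplace) marginal likelihood plus priors; a
    finite-difference Hessian standardizes the axes, and a deterministic
    tensor grid (15 points per dimension for up to two free hyperparameters,
    3 for higher dimensions; configurable via ``spec.grid_points``) is
    evaluated and self-normalized.  Conditional on each grid point the
    latent vector (field, effects, state terms) is Gaussian.
    """
    asm = _Assembled(spec, data, mesh)
    d = len(asm.hyper_names)
    log_post = _hyper_posterior_builder(asm)

    if d == 0:
        params = asm.theta_to_params(np.empty(0))
        cond = _conditional(asm, params)
        return ModelFit(
            spec=spec, asm=asm, mesh=mesh, hyper_names=[],
            theta_mode=np.empty(0),
            grid_thetas=np.empty((1, 0)), grid_weights=np.array([1.0]),
            conditionals=[cond], seed=seed,
        )

    theta0 = asm.initial_theta()
    neg = lambda t: -log_post(t)
    res = optimize.minimize(
        neg, theta0, method="Nelder-Mead",
        options={"xatol": 2e-2, "fatol": 5e-3, "maxiter": 150 * d},
    )
    mode = res.x

    # finite-difference Hessian in theta space
    h = 0.08
    H = np.zeros((d, d))
    f0 = neg(mode)
    for i in range(d):
        for j in range(i, d):
            ei = np.eye(d)[i] * h
            ej = np.eye(d)[j] * h
            if i == j:
                H[i, i] = (neg(mode + ei) - 2 * f0 + neg(mode - ei)) / h**2
            else:
                H[i, j] = H[j, i] = (
                    neg(mode + ei + ej) - neg(mode + ei - ej)
                    - neg(mode - ei + ej) + neg(mode - ei - ej)
                ) / (4 * h**2)
    evals, evecs = np.linalg.eigh(0.5 * (H + H.T))
    evals = np.clip(evals, 1e-4, None)
    scale = evecs @ np.diag(1.0 / np.sqrt(evals))

    g = spec.grid_points if spec.grid_points is not None else (15 if d <= 2 else 3)
    if g == 1:
        zs_1d = np.array([0.0])
    else:
        zs_1d = np.linspace(-spec.grid_halfwidth, spec.grid_halfwidth, g)
        if d > 2 and spec.grid_points is None:
            zs_1d = np.array([-1.65, 0.0, 1.65])
    grids = np.meshgrid(*([zs_1d] * d), indexing="ij")
    Z = np.column_stack([gz.ravel() for gz in grids])
    thetas = mode[None, :] + Z @ scale.T

    lps = np.array([log_post(t) for t in thetas])
    lps = np.where(np.isfinite(lps), lps, -np.inf)
    w = np.exp(lps - lps.max())
    w /= w.sum()
    keep = w > 1e-7
    thetas, w = thetas[keep], w[keep]
    w /= w.sum()

    conditionals = []
    for t in thetas:
        conditionals.append(_conditional(asm, asm.theta_to_params(t)))

    logger.info(
        "fit[%s/%s]: %d obs, latent dim %d, %d grid points",
        spec.name, spec.family, len(asm.y), asm.dim, len(thetas),
    )
    return ModelFit(
        spec=spec, asm=asm, mesh=mesh, hyper_names=asm.hyper_names,
        theta_mode=mode, grid_thetas=thetas, grid_weights=w,
        conditionals=conditionals, seed=seed,
    )


def sample_posterior(fit_result: ModelFit, n: int = 1000, seed: int | None = None) -> dict:
    """Module-level alias for ``ModelFit.sample_posterior``."""
    return fit_result.sample_posterior(n, seed)


# ---------------------------------------------------------------------------
# MCMC oracle


def _split_rhat(x: np.ndarray) -> float:
    half = len(x) // 2
    chains = np.array([x[:half], x[half : 2 * half]])
    m, n = chains.shape
    means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W)) if W > 0 else np.inf


def ess(x: np.ndarray) -> float:
    """Effective sample size via the initial-positive-sequence estimator."""
    x = np.asarray(x, float)
    n = len(x)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1 :] / (np.arange(n, 0, -1))
    if acf[0] <= 0:
        return float(n)
    rho = acf / acf[0]
    s = 0.0
    for k in range(1, n - 1, 2):
        pair = rho[k] + rho[k + 1] if k + 1 < n else rho[k]
        if pair < 0:
            break
        s += pair
    return float(n / (1.0 + 2.0 * s))


def mcmc_oracle(
    spec: ModelSpec,
    data: pd.DataFrame,
    mesh: Mesh | None = None,
    iterations: int = 4000,
    seed: int = 0,
    burn: int | None = None,
    step: float = 0.12,
) -> dict:
    """Metropolis-within-Gibbs sampler over the same hierarchical model.

    Latent vector: exact Gaussian Gibbs draw (lognormal family) or
    independence Metropolis from the Laplace approximation (gamma family);
    hyperparameters: random-walk Metropolis on the log scale.  Small
    instances only — this is the independent inference oracle used in tests.
    Reports split-R-hat and effective sample sizes; R-hat > 1.1 warns.
    """
    asm = _Assembled(spec, data, mesh)
    if asm.dim > 1200:
        raise ValueError("mcmc_oracle is restricted to small instances")
    rng = np.random.default_rng(seed)
    burn = iterations // 4 if burn is None else burn
    d = len(asm.hyper_names)
    theta = asm.initial_theta()

    def log_prior_latent(x, params, Q=None):
        Q = asm.prior_precision(params) if Q is None else Q
        dx = x - asm.mu0
        return 0.5 * asm.logdet_prior(params) - 0.5 * float(dx @ (Q @ dx))

    cond = _conditional(asm, asm.theta_to_params(theta))
    x = cond.mu.copy()
    keep_latent = np.zeros((iterations - burn, asm.dim))
    keep_theta = np.zeros((iterations - burn, d))
    n_acc = 0

    params = asm.theta_to_params(theta)
    lp_lat = log_prior_latent(x, params)
    ll = asm.loglik(asm.A @ x, params).sum() + asm.log_hyper_prior(theta)

    for it in range(iterations):
        # --- latent update
        cond = _conditional(asm, params, x_init=x)
        if asm.spec.family == "lognormal":
            x = cond.sample(1, rng)[0]
        else:
            prop = cond.sample(1, rng)[0]

            def laplace_logq(v):
                dv = v - cond.mu
                Hf = cond.factor()
                return -0.5 * float(dv @ (asm.prior_precision(params) @ dv)) - 0.5 * float(
                    dv @ (asm.A.T @ (cond.D * (asm.A @ dv)))
                )

            lt_prop = asm.loglik(asm.A @ prop, params).sum() + log_prior_latent(prop, params)
            lt_cur = asm.loglik(asm.A @ x, params).sum() + log_prior_latent(x, params)
            if math.log(rng.uniform()) < (lt_prop - lt_cur) - (
                laplace_logq(prop) - laplace_logq(x)
            ):
                x = prop
        lp_lat = log_prior_latent(x, params)
        ll = asm.loglik(asm.A @ x, params).sum() + asm.log_hyper_prior(theta)

        # --- hyperparameter update
        if d:
            theta_prop = theta + step * rng.standard_normal(d)
            params_prop = asm.theta_to_params(theta_prop)
            try:
                lp_lat_prop = log_prior_latent(x, params_prop)
                ll_prop = asm.loglik(asm.A @ x, params_prop).sum() + asm.log_hyper_prior(
                    theta_prop
                )
            except (FloatingPointError, np.linalg.LinAlgError):
                lp_lat_prop, ll_prop = -np.inf, -np.inf
            if math.log(rng.uniform()) < (lp_lat_prop + ll_prop) - (lp_lat + ll):
                theta, params = theta_prop, params_prop
                lp_lat, ll = lp_lat_prop, ll_prop
                n_acc += 1

        if it >= burn:
            keep_latent[it - burn] = x
            keep_theta[it - burn] = theta

    beta = keep_latent[:, asm.sl_beta]
    rhat = _split_rhat(beta[:, 0])
    if rhat > 1.1:
        logger.warning("mcmc_oracle: split-Rhat %.3f > 1.1 for intercept", rhat)
    out = {
        "latent": keep_latent,
        "beta": beta,
        "field": keep_latent[:, asm.sl_w],
        "state": keep_latent[:, asm.sl_u],
        "theta_log": keep_theta,
        "hyper_names": asm.hyper_names,
        "accept_rate": n_acc / max(iterations, 1),
        "rhat_intercept": rhat,
        "ess_intercept": ess(beta[:, 0]),
    }
    for j, nm in enumerate(asm.hyper_names):
        out[nm] = np.exp(keep_theta[:, j])
    return out
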