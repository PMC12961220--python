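# Methods

This note records the statistical model, the numerical choices behind the
implementation, what the synthetic-data generator does and does not
emulate, and the known limitations. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Hierarchical model

Observed concentrations `y_i > 0` at sites `s_i` follow either

- **lognormal**: `log y_i ~ Normal(η_i, σ_obs²)`, or
- **gamma**: `y_i ~ Gamma(shape φ, mean exp(η_i))`,

with the log-scale linear predictor

```
η_i = β₀ + x_iᵀ β + w(s_i) + u_state(i)
```

`x_i` are covariates standardized to mean 0 / sample SD 1 (the scaling
record is stored and reused verbatim at prediction time — the fixed effects
are defined on the training scale). `u_state` are exchangeable per-state
intercepts with a Gamma(shape 1, rate 5·10⁻⁵) prior on their precision (the
conventional weak default for iid effects in this model family). `w(s)` is
a zero-mean Matérn field with smoothness ν = 1 — the conventional 2-D
default (SPDE operator order α = 2) — range ρ and marginal SD σ.

### SPDE finite-element representation

On a triangulation with P1 elements, the lumped mass matrix `C` (diagonal,
`C_ii` = one third of the area of the triangles incident to node i) and
stiffness matrix `G` define the precision of the node weights:

```
Q(ρ, σ) = τ² (κ⁴ C + 2 κ² G + G C⁻¹ G) = τ² Mᵀ C⁻¹ M,   M = κ² C + G
κ = √8 / ρ,    τ² = 1 / (4π κ² σ²)
```

so that the marginal variance of the field is σ² and the correlation decays
to ≈ 0.1 around distance ρ (the ν = 1 closed form `(κd)·K₁(κd)` equals
0.1397 exactly at d = ρ; "0.1 at the range" is the field's conventional
shorthand). Observations and prediction cells connect to the nodes through
sparse barycentric projection matrices. The factored form `τ² Mᵀ C⁻¹ M` is
used for prior log-determinants and for prior sampling by solving with `M`.

### Priors

| parameter | prior | default |
|---|---|---|
| range ρ | PC, density λρ⁻² e^(−λ/ρ), λ = −u·ln α, P(ρ<u)=α | u = half the x-extent of the data ("range_ob"), α = 0.5 |
| field SD σ | PC exponential, λ = −ln(α)/u, P(σ>u)=α | (0.5, 0.5) |
| β₀, β | Normal(mean, precision) | (0, 10⁻⁴), the weakly-informative baseline; the sensitivity suite sweeps 10⁻² … 10⁻⁶ |
| state precision | Gamma(shape, rate) | (1, 5·10⁻⁵) |
| σ_obs (lognormal) | PC exponential | P(σ_obs > 1) = 0.1 — chosen weakly informative; the reference implementation's internal default is not published, so ours is documented rather than claimed identical |
| φ (gamma shape) | Gamma(shape, rate) | (1, 0.1), weakly informative on the positive axis |

All prior hyperparameters are fields of `ModelSpec`; any hyperparameter can
also be pinned via `fixed_hyper`, which the closed-form test oracles use.

## Inference: deterministic hyperparameter-grid integration

Let θ collect the log-transformed free hyperparameters (up to four: log ρ,
log σ, log σ_obs or log φ, log τ_state).

1. **Marginal likelihood.** For the lognormal family, conditional on θ the
   latent vector `x = (w, β, u)` is exactly Gaussian: posterior precision
   `H = Q_x(θ) + AᵀA/σ_obs²` with `A` the full design, and the marginal
   likelihood of the log-responses is available in closed form from the two
   log-determinants and the quadratic form. For the gamma family an inner
   Newton iteration (log-concave likelihood, damped steps) finds the
   conditional mode and the Laplace approximation supplies the marginal.
2. **Mode and scale.** Nelder-Mead maximizes the θ-posterior; a central
   finite-difference Hessian (step 0.08, eigenvalue floor 10⁻⁴)
   standardizes the axes.
3. **Grid.** A tensor grid in the standardized space: 15 points per
   dimension spanning ±3 SD when at most two hyperparameters are free,
   3 points (z ∈ {−1.65, 0, +1.65}) per dimension otherwise — a deliberate
   accuracy/cost trade at desk scale, configurable via
   `ModelSpec.grid_points`. Weights are the self-normalized posterior
   values; points below 10⁻⁷ relative weight are pruned. A self-consistency
   experiment in the test suite (GMRF-simulated fields refitted on their own
   mesh) shows the 3-point grid recovers the generating range without
   detectable bias, and refitting with 5 points per dimension moves the
   posterior-mean range by under 3%.
4. **Summaries and draws.** Posterior means mix the conditional means over
   grid weights. Joint draws first sample a grid point by weight, then draw
   the latent conditional by Matheron's rule (prior draw via `M`-solves plus
   a kriging correction through one `H`-solve), so only sparse/dense solves
   are needed — no explicit square root of `H`. Factorizations are rebuilt
   per use and released immediately; caching one per grid point would
   dominate memory on fine meshes.

Dense Cholesky is used for latent dimensions up to 700, SuperLU beyond;
both paths are exact and the switch is invisible to callers. The prior
log-determinant uses the generalized eigenvalues of the (C, G) pencil,
precomputed once per mesh up to 1500 nodes, and a factorization of `M`
otherwise.

### MCMC oracle

`mcmc_oracle` targets the same posterior by Metropolis-within-Gibbs:
exact Gaussian Gibbs updates of the latent vector (lognormal) or
independence-Metropolis proposals from the Laplace approximation (gamma),
and random-walk Metropolis on log θ (default step 0.12). It reports
split-R̂ (warning above 1.1) and an autocorrelation-based effective sample
size. It shares only the model definition with the grid engine — none of
the integration machinery — and is used in tests to bound the grid
posterior means within two Monte-Carlo standard errors.

## Model comparison and validation

- **WAIC** uses the variance form: `−2 Σ_i [log E_s p(y_i|s) −
  Var_s log p(y_i|s)]` over joint posterior draws (hyperparameter draws
  included). **DIC** uses the posterior-mean plug-in deviance. **LCPO** is
  `−mean log CPO_i`; lower is better for all three, and rankings prioritize
  WAIC with LCPO (or DIC) as tie-break.
- **CPO / LOO / LGO.** For the lognormal family the leave-out predictive
  densities are exact per grid point: the marginal covariance of the
  log-responses is inverted by a Woodbury downdate of `H`, and Gaussian
  conditioning on the retained observations gives each held-out density;
  grid points mix through `1/CPO_i = Σ_g w_g / p_g(y_i | y_−i)`. For the
  gamma family, importance weighting over draws is used with a brute-force
  refit fallback whenever one weight exceeds 0.2 of the total. LGO groups
  are the observation plus its (group size − 1) nearest neighbours, removed
  jointly, with group sizes 6, 8 or 10.
- **Posterior predictive checks** simulate full replicate datasets from
  joint draws and compare mean, median, variance and 90th quantile of the
  data against their 95% simulated intervals.
- **Sensitivity suites** refit under mesh fractions 1/5, 1/10, 1/15 of the
  estimated range, a cutoff override (e.g. 0.5 km), and the fixed-effect /
  PC prior tables; WAIC differences under 10 units are flagged equivalent.

## Meshes

The coarse (model-selection) mesh derives everything from the x-extent of
the data: inner max edge = extent/12, outer offset = extent/3, outer edge =
5× inner, cutoff = inner/5; the fine mesh sets the inner edge to 1/10 of
the estimated range (1/5 and 1/15 are the sensitivity variants). The
y-extent is deliberately not used — the heuristics are stated in terms of
the x-extent alone.

Construction: data points are cutoff-thinned greedily in input order; a
hexagonal lattice at 0.78× the max edge fills the study area plus a small
collar (1.2 lattice spacings) past the boundary; the buffer ring out to the
offset is filled at the outer spacing plus a densified outer ring; the
union is Delaunay-triangulated and triangles are flagged inner by centroid
containment. The lattice spacing is set so the covering-radius bound keeps
every inner Delaunay edge below the max-edge parameter (verified with 1%
tolerance in the tests). No attempt is made to reproduce any particular
mesher's node placement; the contracts (max edge, containment, monotone
refinement, projection-row identities) are the interface. Thin boundary
slivers can make the global minimum angle small; this affects neither the
SPD property of the FEM matrices nor the max-edge contract.

## Synthetic data: what it emulates, what it does not

The generator produces (a) a rectangular study domain tiled into states,
(b) smooth standardized covariate rasters (Gaussian-filtered noise plus a
small rough component; one pair can be constructed with an exact target
correlation for screening tests), (c) a two-horizon point survey from the
exact hierarchical model above — Matérn field simulated densely from the
ν = 1 closed form at the site locations, iid state effects, lognormal or
gamma observation noise — with below-detection flags against a configurable
LLD and optional "N.S." lab codes, horizon pairs as the response plus
independent N(0, 0.05²) perturbations, and (d) the full generating record
(`SyntheticTruth`) for recovery tests.

Default study conditions used by the recovery tests: 1200×800 km domain,
4×3 states, 400 sites, β = (2.3 | 0.5, −0.3, 0.2), range 300 km, σ = 0.8,
state SD 0.15, σ_obs = 0.3, covariate correlation length ≈ 60 km. These
mimic a continental-scale survey at low site density (1 site per ~2400
km²) with positively skewed concentrations around 10 mg/kg.

Not emulated: real SSURGO/PRISM/NLCD spatial texture, anisotropy,
non-stationarity, real coastline/state geometry, any true CRS, measurement
batch effects. Passing recovery tests therefore demonstrates correctness of
the estimation machinery under the model's own assumptions, not robustness
to the ways real soil data violate them.

## Problem sizes in the test suite

The statistical acceptance tests run at deliberately reduced scale, chosen
as the smallest configurations at which the properties under test are
identifiable: model selection on a reduced coarse mesh (inner edge =
extent/8, ≈ 400 nodes) over 20 replicates of the default study conditions;
recovery via the two-stage workflow — coarse fit, then a 1/10-range fine
mesh (1000–2700 nodes) with the range-model prior — matching how the
method is meant to be deployed; predictive calibration over 40 replicates
at 150 sites on a 600×400 km domain; mesh sensitivity over 10 replicates;
MCMC-oracle agreement on ≤300-node toys with 4000 iterations.

## Numerical choices and degenerate inputs

- Collinearity screen: strict `|r| > 0.7`, later-listed covariate dropped,
  zero-variance covariates dropped with a warning.
- Decile maps: breaks at the 10%…100% quantiles of the reference raster
  (the posterior mean, also for the credible-bound layers); values exactly
  on a break go to the lower class; constant rasters raise.
- Response-scale prediction: per-draw expected response — `exp(η + σ_obs²/2)`
  for the lognormal family (the lognormal mean, not the median), `exp(η)`
  for gamma — summarized by mean and 2.5/97.5% quantiles over draws.
- Below-detection values: replaced by LLD/2; a flagged value without an
  LLD is an error, not a silent pass.
- Duplicate grid assignment for a sample exactly on a cell edge is resolved
  by a seeded random choice so exactly one record is retained.
- Degenerate triangles, singular designs (with the aliased columns named),
  non-positive responses, and cutoffs at or above the max edge all raise
  immediately.
- Gamma Newton inner loop: damped steps with a 60-iteration cap, working
  weights clipped to [10⁻¹⁰, 10¹⁰]; divergence raises rather than returning
  a silent half-converged fit.

## Known limitations

- The spatial range and field SD are weakly identified when the domain
  spans only a few correlation ranges: their joint posterior concentrates
  along a ridge and posterior means are prior-sensitive and upward-skewed.
  The two-stage coarse-to-fine workflow reduces but does not remove this;
  tests therefore assess the range by replicate averages and the fixed
  effects by credible-interval coverage.
- The gamma path is Laplace-approximate; its small skew bias is bounded in
  tests against the MCMC oracle but not corrected.
- The 3-point hyperparameter grid (for ≥3 free hyperparameters) captures
  location and scale of the hyperparameter posterior but not heavy tails;
  increase `grid_points` when tail quantiles of hyperparameters matter.
- LGO cross-validation with the refit fallback is O(n) refits in the worst
  case and is intended for desk-scale model criticism, not production runs
  over thousands of sites.
- ESRI ASCII rasters carry no CRS metadata; the kilometre frame is a
  package convention (×1000 to metres on export).
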