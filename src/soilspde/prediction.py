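"""Posterior prediction surfaces, rasterization and percentile maps.

Predictions standardize the covariate grids with the *training* scaling
record (the fixed effects are defined on that scale), propagate joint
posterior draws of (beta, w, u, hyperparameters) to every grid cell, and
summarize the response-scale concentration by its posterior mean and 95%
credible bounds.  The response-scale value of a draw is the expected
concentration under that draw: exp(eta + sigma_obs^2/2) for the lognormal
family, exp(eta) for the gamma family.  Rasters are masked to the study
boundary and exported in metres (x1000) as plain-text grids; decile maps
reuse the posterior-mean breaks for the credible-bound surfaces.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely

from .ingest import ScalingRecord
from .mesh import projection_matrix
from .rasters import CovariateRasterSet, Raster, write_ascii_grid
from .spde_model import ModelFit

logger = logging.getLogger(__name__)

__all__ = [
    "PredictionSurface",
    "PercentileMap",
    "predict_surface",
    "project_field",
    "rasterize",
    "percentile_classify",
]

_CHUNK = 20000


@dataclass
class PredictionSurface:
    """Posterior mean and 95% CI of the concentration on a grid.

    Arrays are north-up and share the template raster's georeferencing;
    cells without predictions (missing covariates, outside mesh/boundary)
    are NaN in all three layers.
    """

    mean: Raster
    lower: Raster
    upper: Raster

    def __post_init__(self) -> None:
        ok = np.isfinite(self.mean.data)
        if not (
            np.all(self.lower.data[ok] <= self.mean.data[ok] + 1e-9)
            and np.all(self.mean.data[ok] <= self.upper.data[ok] + 1e-9)
        ):
            raise ValueError("credible bounds must bracket the mean")

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.mean.data)


def _state_lookup(states: dict[str, object] | None, levels: list[str],
                  x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Column index into the state-effect vector per cell; -1 when no state."""
    idx = np.full(len(x), -1, dtype=int)
    if not states or not levels:
        return idx
    pos = {s: i for i, s in enumerate(levels)}
    keys = list(states)
    tree = shapely.STRtree([states[k] for k in keys])
    pts = shapely.points(np.column_stack([x, y]))
    qi, ti = tree.query(pts, predicate="intersects")
    for p, t in zip(qi, ti):
        if idx[p] == -1:
            idx[p] = pos.get(keys[t], -1)
    return idx


def predict_surface(
    fit: ModelFit,
    covariates: CovariateRasterSet,
    scaling: ScalingRecord,
    states: dict[str, object] | None = None,
    boundary=None,
    n_draws: int = 1000,
    seed: int | None = None,
) -> PredictionSurface:
    """Response-scale posterior mean and 2.5/97.5% bounds per grid cell.

    Cells with any missing covariate are masked; cells outside the mesh are
    masked with a warning count.  ``states`` maps state ids to polygons so
    each cell receives the effect of its containing state (cells outside
    every training state get no state contribution).
    """
    template = covariates.template()
    cx, cy = template.cell_centers()
    x, y = cx.ravel(), cy.ravel()

    defined = ~covariates.missing_mask().ravel()
    if boundary is not None:
        shapely.prepare(boundary)
        defined &= shapely.covers(boundary, shapely.points(np.column_stack([x, y])))
    idx = np.where(defined)[0]

    cov_names = list(fit.spec.covariates)
    Xc = np.column_stack(
        [np.ones(idx.size)]
        + [
            (covariates[nm].data.ravel()[idx] - scaling.means[nm]) / scaling.sds[nm]
            for nm in cov_names
        ]
    )

    draws = fit.sample_posterior(n_draws, seed)
    beta = draws["beta"]
    n_s = len(draws["latent"])
    if fit.spec.family == "lognormal":
        half_var = 0.5 * draws["sigma_obs"] ** 2
    else:
        half_var = np.zeros(n_s)

    if fit.spec.include_spatial:
        A_pred = projection_matrix(fit.mesh, np.column_stack([x[idx], y[idx]]))
        in_mesh = np.asarray(A_pred.sum(axis=1)).ravel() > 0
        n_out = int((~in_mesh).sum())
        if n_out:
            logger.warning("predict_surface: %d cells outside mesh masked", n_out)
    else:
        A_pred = None
        in_mesh = np.ones(idx.size, dtype=bool)

    st_idx = _state_lookup(states, fit.asm.state_levels, x[idx], y[idx])
    u = draws["state"]

    mean = np.full(x.size, np.nan)
    lo = np.full(x.size, np.nan)
    hi = np.full(x.size, np.nan)
    for start in range(0, idx.size, _CHUNK):
        sl = slice(start, min(start + _CHUNK, idx.size))
        eta = Xc[sl] @ beta.T  # (cells, draws)
        if A_pred is not None:
            eta += np.asarray((A_pred[sl] @ draws["field"].T))
        has_state = st_idx[sl] >= 0
        if u.size and has_state.any():
            eta[has_state] += u.T[np.clip(st_idx[sl][has_state], 0, None)]
        resp = np.exp(eta + half_var[None, :])
        resp[~in_mesh[sl]] = np.nan
        cells = idx[sl]
        mean[cells] = resp.mean(axis=1)
        q = np.nanquantile(resp, [0.025, 0.975], axis=1)
        lo[cells], hi[cells] = q[0], q[1]

    shp = template.shape
    return PredictionSurface(
        mean=template.copy_with(mean.reshape(shp)),
        lower=template.copy_with(lo.reshape(shp)),
        upper=template.copy_with(hi.reshape(shp)),
    )


def project_field(fit: ModelFit, template: Raster) -> Raster:
    """Posterior mean of the spatial random field w(s) at cell centers.

    On the response scale the field acts multiplicatively: a cell value v
    scales the expected concentration by exp(v).  Cells outside the mesh
    are missing.
    """
    if not fit.spec.include_spatial:
        raise ValueError("model has no spatial field")
    cx, cy = template.cell_centers()
    pts = np.column_stack([cx.ravel(), cy.ravel()])
    A = projection_matrix(fit.mesh, pts)
    vals = np.asarray(A @ fit.field_mean())
    outside = np.asarray(A.sum(axis=1)).ravel() == 0
    vals[outside] = np.nan
    return template.copy_with(vals.reshape(template.shape))


def rasterize(
    surface: Raster | PredictionSurface,
    template: Raster,
    boundary,
    path: str | Path | None = None,
) -> Raster:
    """Mask a surface to the study boundary on the template grid.

    When ``path`` is given the raster is also written as an ESRI ASCII grid
    with coordinates converted from km to metres (x1000).
    """
    r = surface.mean if isinstance(surface, PredictionSurface) else surface
    if not r.same_grid(template):
        raise ValueError("surface is not aligned to the template grid")
    cx, cy = template.cell_centers()
    shapely.prepare(boundary)
    inside = shapely.covers(
        boundary, shapely.points(np.column_stack([cx.ravel(), cy.ravel()]))
    ).reshape(template.shape)
    out = template.copy_with(np.where(inside, r.data, np.nan))
    if path is not None:
        write_ascii_grid(out, path, scale=1000.0)
    return out


@dataclass
class PercentileMap:
    """Decile classification of a continuous surface.

    ``breaks`` are the 10 upper class bounds (10%..100% quantiles of the
    reference raster); class k covers values in (breaks[k-2], breaks[k-1]]
    with boundary values assigned to the lower class.  ``classified`` holds
    integer classes 1-10 (NaN where undefined); labels carry the raw
    concentration ranges.
    """

    breaks: np.ndarray
    labels: list[str]
    classified: Raster

    def write_labels(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"breaks": self.breaks.tolist(), "labels": self.labels})
        )


def percentile_classify(
    raster: Raster, reference: Raster | None = None
) -> PercentileMap:
    """Bin a raster into ten percentile classes (10-100%).

    ``reference`` supplies the class breaks (default: the raster itself);
    credible-bound rasters are classified with the posterior mean's breaks,
    so their class counts need not be equal.
    """
    ref = reference if reference is not None else raster
    ref_vals = ref.data[np.isfinite(ref.data)]
    if ref_vals.size < 10:
        raise ValueError("need at least 10 defined values to build deciles")
    breaks = np.quantile(ref_vals, np.linspace(0.1, 1.0, 10))
    if np.any(np.diff(breaks) <= 0):
        raise ValueError("degenerate decile breaks (too many tied values)")
    vals = raster.data
    classes = np.full(vals.shape, np.nan)
    ok = np.isfinite(vals)
    classes[ok] = np.searchsorted(breaks[:9], vals[ok], side="left") + 1
    lo = float(min(ref_vals.min(), vals[ok].min() if ok.any() else np.inf))
    edges = np.concatenate([[lo], breaks])
    labels = [
        f"{10 * (k + 1)}%: {edges[k]:.4g}-{edges[k + 1]:.4g}" for k in range(10)
    ]
    return PercentileMap(
        breaks=breaks, labels=labels, classified=raster.copy_with(classes)
    )
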