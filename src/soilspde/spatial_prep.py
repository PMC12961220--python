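"""Sampling grid, raster alignment, zonal extraction and spatial joins.

Everything operates in a projected kilometre frame.  The sampling grid is a
regular square tessellation anchored at the lower-left corner of the study
boundary's bounding box; covariate rasters are aligned to it by area-weighted
aggregation (finer to coarser) or bilinear interpolation (coarser to finer),
and per-cell zonal means feed the modeling table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.interpolate import RegularGridInterpolator

from .rasters import CovariateRasterSet, Raster

logger = logging.getLogger(__name__)

__all__ = [
    "SamplingGrid",
    "build_sampling_grid",
    "align_rasters",
    "zonal_mean_extract",
    "join_samples_to_grid",
    "filter_within_boundary",
]


@dataclass
class SamplingGrid:
    """Square-cell sampling grid with a per-cell in-domain flag (north-up)."""

    x0: float
    y0: float
    edge: float
    n_cols: int
    n_rows: int
    in_domain: np.ndarray  # bool, shape (n_rows, n_cols), row 0 = top

    @property
    def cell_area(self) -> float:
        return self.edge**2

    def template_raster(self) -> Raster:
        return Raster(np.zeros((self.n_rows, self.n_cols)), self.x0, self.y0, self.edge)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        return self.template_raster().cell_centers()

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of containing cell, north-up; -1 outside the grid."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        col = np.floor((x - self.x0) / self.edge).astype(int)
        rowb = np.floor((y - self.y0) / self.edge).astype(int)
        row = self.n_rows - 1 - rowb
        bad = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        col[bad] = -1
        row[bad] = -1
        return row, col


def build_sampling_grid(boundary, cell_area_km2: float = 6.0) -> SamplingGrid:
    """Square grid of ``sqrt(cell_area)``-edge cells covering the boundary's
    bounding box; cells intersecting the boundary are flagged in-domain.

    The default 6 km^2 cell gives the 2.449 km edge of the national grid.
    """
    if cell_area_km2 <= 0:
        raise ValueError("cell_area_km2 must be positive")
    if boundary is None or boundary.is_empty or boundary.area <= 0:
        raise ValueError("degenerate boundary polygon")
    edge = float(np.sqrt(cell_area_km2))
    xmin, ymin, xmax, ymax = boundary.bounds
    n_cols = int(np.ceil((xmax - xmin) / edge - 1e-12))
    n_rows = int(np.ceil((ymax - ymin) / edge - 1e-12))
    xs = xmin + np.arange(n_cols) * edge
    ys_bottom = ymin + np.arange(n_rows) * edge
    gx, gy = np.meshgrid(xs, ys_bottom)
    boxes = shapely.box(gx.ravel(), gy.ravel(), gx.ravel() + edge, gy.ravel() + edge)
    shapely.prepare(boundary)
    inside = shapely.intersects(boundary, boxes).reshape(n_rows, n_cols)
    in_domain = np.flipud(inside)  # to north-up
    return SamplingGrid(xmin, ymin, edge, n_cols, n_rows, in_domain)


def _axis_overlap(
    start_dst: float, cell_dst: float, n_dst: int,
    start_src: float, cell_src: float, n_src: int,
) -> np.ndarray:
    """(n_dst, n_src) matrix of interval overlap lengths along one axis."""
    d0 = start_dst + np.arange(n_dst)[:, None] * cell_dst
    d1 = d0 + cell_dst
    s0 = start_src + np.arange(n_src)[None, :] * cell_src
    s1 = s0 + cell_src
    return np.clip(np.minimum(d1, s1) - np.maximum(d0, s0), 0.0, None)


def _area_weighted_to_grid(src: Raster, template: Raster) -> np.ndarray:
    """Area-weighted mean of src cells within each template cell (north-up out).

    Missing src cells carry zero weight; a template cell with no valid
    overlap is missing.
    """
    wx = _axis_overlap(template.x0, template.cell, template.n_cols,
                       src.x0, src.cell, src.n_cols)
    wy = _axis_overlap(template.y0, template.cell, template.n_rows,
                       src.y0, src.cell, src.n_rows)
    data_bu = np.flipud(src.data)  # bottom-up rows to match ascending y
    valid = np.isfinite(data_bu)
    num = wy @ np.where(valid, data_bu, 0.0) @ wx.T
    den = wy @ valid.astype(float) @ wx.T
    with np.errstate(invalid="ignore", divide="ignore"):
        out_bu = np.where(den > 0, num / den, np.nan)
    return np.flipud(out_bu)


def _bilinear_to_grid(src: Raster, template: Raster) -> np.ndarray:
    xs = src.x0 + (np.arange(src.n_cols) + 0.5) * src.cell
    ys = src.y0 + (np.arange(src.n_rows) + 0.5) * src.cell
    interp = RegularGridInterpolator(
        (ys, xs), np.flipud(src.data), bounds_error=False, fill_value=None
    )
    cx, cy = template.cell_centers()
    # clamp to the src center range: nearest-edge extension, no extrapolation
    pts = np.column_stack([
        np.clip(cy.ravel(), ys[0], ys[-1]),
        np.clip(cx.ravel(), xs[0], xs[-1]),
    ])
    return interp(pts).reshape(template.shape)


def align_rasters(
    rasters: dict[str, Raster] | CovariateRasterSet,
    template: Raster | SamplingGrid,
) -> CovariateRasterSet:
    """Resample every raster onto the template grid.

    Finer-than-template rasters are aggregated by area-weighted means
    (e.g. a crop-cover indicator becomes a per-cell proportion); coarser
    rasters are interpolated bilinearly.  Already-aligned rasters pass
    through unchanged.
    """
    if isinstance(template, SamplingGrid):
        template = template.template_raster()
    if isinstance(rasters, CovariateRasterSet):
        rasters = rasters.rasters
    out: dict[str, Raster] = {}
    for name, src in rasters.items():
        sx0, sy0, sx1, sy1 = src.extent
        tx0, ty0, tx1, ty1 = template.extent
        if sx1 <= tx0 or sx0 >= tx1 or sy1 <= ty0 or sy0 >= ty1:
            raise ValueError(f"raster {name!r} does not overlap the template extent")
        if src.same_grid(template):
            out[name] = src.copy_with(src.data.copy())
        elif src.cell <= template.cell:
            out[name] = template.copy_with(_area_weighted_to_grid(src, template))
        else:
            out[name] = template.copy_with(_bilinear_to_grid(src, template))
    aligned = CovariateRasterSet(out)
    for name, r in aligned.rasters.items():
        assert r.shape == template.shape, f"alignment failed for {name!r}"
    return aligned


def zonal_mean_extract(raster: Raster, grid: SamplingGrid) -> Raster:
    """Overlap-weighted mean of raster values within each grid cell.

    Fully-missing zones propagate as missing.
    """
    template = grid.template_raster()
    return template.copy_with(_area_weighted_to_grid(raster, template))


def join_samples_to_grid(
    samples: pd.DataFrame,
    grid: SamplingGrid,
    covariates: CovariateRasterSet,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Attach each sample to its containing cell's covariates.

    A sample lying exactly on a cell edge intersects two (or four) cells;
    one containing cell is chosen with the seeded RNG so exactly one record
    is retained.  Samples outside the grid, and samples in cells with any
    missing covariate, are dropped and counted.
    """
    covariates.validate_aligned()
    if not covariates.template().same_grid(grid.template_raster()):
        raise ValueError("covariates are not aligned to the sampling grid")
    rng = np.random.default_rng(seed)
    x = samples["x_km"].to_numpy(float)
    y = samples["y_km"].to_numpy(float)

    fx = (x - grid.x0) / grid.edge
    fy = (y - grid.y0) / grid.edge
    col = np.floor(fx).astype(int)
    rowb = np.floor(fy).astype(int)
    tol = 1e-9
    for frac, idx, n in ((fx, col, grid.n_cols), (fy, rowb, grid.n_rows)):
        near = np.abs(frac - np.round(frac)) < tol
        interior = near & (np.round(frac) > 0) & (np.round(frac) < n)
        # on an interior edge: the point belongs to both adjacent cells;
        # keep one record, choosing the cell at random
        k = np.round(frac[interior]).astype(int)
        pick_lower = rng.integers(0, 2, size=int(interior.sum())).astype(bool)
        idx[interior] = np.where(pick_lower, k - 1, k)
    row = grid.n_rows - 1 - rowb

    outside = (col < 0) | (col >= grid.n_cols) | (row < 0) | (row >= grid.n_rows)
    for sid in samples.loc[outside, "site_id"]:
        logger.info("join_samples_to_grid: site %s outside grid, dropped", sid)

    out = samples.loc[~outside].copy()
    r, c = row[~outside], col[~outside]
    missing_any = np.zeros(len(out), dtype=bool)
    for name in covariates.names:
        vals = covariates[name].data[r, c]
        out[name] = vals
        missing_any |= ~np.isfinite(vals)
    out["grid_row"] = r
    out["grid_col"] = c
    report = {
        "outside_grid": int(outside.sum()),
        "missing_covariate": int(missing_any.sum()),
    }
    if report["missing_covariate"]:
        logger.info(
            "join_samples_to_grid: dropped %d samples with missing covariates",
            report["missing_covariate"],
        )
    return out.loc[~missing_any].reset_index(drop=True), report


def filter_within_boundary(
    samples: pd.DataFrame, boundary
) -> tuple[pd.DataFrame, int]:
    """Keep samples inside or on the study boundary; report the removal count.

    Containment is closed (a point on the boundary edge counts as inside)
    so coastal sites are not silently lost.
    """
    if boundary is None or boundary.is_empty:
        raise ValueError("invalid boundary polygon")
    pts = shapely.points(
        samples["x_km"].to_numpy(float), samples["y_km"].to_numpy(float)
    )
    shapely.prepare(boundary)
    keep = shapely.covers(boundary, pts)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filter_within_boundary: removed %d samples", n_removed)
    return samples.loc[keep].reset_index(drop=True), n_removed
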