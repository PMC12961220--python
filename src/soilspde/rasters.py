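"""Lightweight georeferenced grid container and plain-text raster I/O.

Rasters live in a projected kilometre coordinate frame.  Arrays are stored
north-up: row 0 is the top (largest y), consistent with the ESRI ASCII grid
layout used for serialization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Raster", "CovariateRasterSet", "read_ascii_grid", "write_ascii_grid"]

_NODATA = -9999.0


@dataclass
class Raster:
    """A single-band raster on a regular square grid.

    Parameters
    ----------
    data : 2-D float array, north-up (row 0 = top row).
    x0, y0 : coordinates of the lower-left corner of the grid, km.
    cell : cell edge length, km.
    """

    data: np.ndarray
    x0: float
    y0: float
    cell: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.cell <= 0:
            raise ValueError("cell size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in km."""
        return (
            self.x0,
            self.y0,
            self.x0 + self.n_cols * self.cell,
            self.y0 + self.n_rows * self.cell,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinates; same north-up shape as ``data``."""
        xs = self.x0 + (np.arange(self.n_cols) + 0.5) * self.cell
        ys = self.y0 + (self.n_rows - np.arange(self.n_rows) - 0.5) * self.cell
        return np.meshgrid(xs, ys)

    def copy_with(self, data: np.ndarray) -> "Raster":
        if data.shape != self.data.shape:
            raise ValueError("replacement data shape mismatch")
        return Raster(np.asarray(data, float), self.x0, self.y0, self.cell)

    def same_grid(self, other: "Raster", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.x0 - other.x0) <= tol
            and abs(self.y0 - other.y0) <= tol
            and abs(self.cell - other.cell) <= tol
        )

    def sample(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Nearest-cell lookup at point coordinates; NaN outside the grid."""
        x = np.atleast_1d(np.asarray(x, float))
        y = np.atleast_1d(np.asarray(y, float))
        col = np.floor((x - self.x0) / self.cell).astype(int)
        row_from_bottom = np.floor((y - self.y0) / self.cell).astype(int)
        row = self.n_rows - 1 - row_from_bottom
        out = np.full(x.shape, np.nan)
        ok = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        out[ok] = self.data[row[ok], col[ok]]
        return out


@dataclass
class CovariateRasterSet:
    """Named rasters sharing one grid (after alignment)."""

    rasters: dict[str, Raster] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate_aligned()

    @property
    def names(self) -> list[str]:
        return list(self.rasters)

    def __getitem__(self, name: str) -> Raster:
        return self.rasters[name]

    def __len__(self) -> int:
        return len(self.rasters)

    def validate_aligned(self) -> None:
        rs = list(self.rasters.values())
        for r in rs[1:]:
            if not rs[0].same_grid(r):
                raise ValueError("covariate rasters are not aligned to one grid")

    def template(self) -> Raster:
        return next(iter(self.rasters.values()))

    def missing_mask(self) -> np.ndarray:
        """True where any covariate is missing."""
        m = np.zeros(self.template().shape, dtype=bool)
        for r in self.rasters.values():
            m |= ~np.isfinite(r.data)
        return m


def write_ascii_grid(raster: Raster, path: str | Path, scale: float = 1.0) -> None:
    """Write an ESRI ASCII grid.  ``scale`` rescales coordinates on export
    (e.g. 1000.0 to convert the km frame to metres)."""
    path = Path(path)
    d = np.where(np.isfinite(raster.data), raster.data, _NODATA)
    header = (
        f"ncols {raster.n_cols}\n"
        f"nrows {raster.n_rows}\n"
        f"xllcorner {raster.x0 * scale:.6f}\n"
        f"yllcorner {raster.y0 * scale:.6f}\n"
        f"cellsize {raster.cell * scale:.6f}\n"
        f"NODATA_value {_NODATA:g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, d, fmt="%.17g")


def read_ascii_grid(path: str | Path, scale: float = 1.0) -> Raster:
    """Read an ESRI ASCII grid; ``scale`` divides coordinates on import."""
    path = Path(path)
    meta: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            meta[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    nodata = meta.get("nodata_value", _NODATA)
    data = np.where(data == nodata, np.nan, data)
    return Raster(
        data,
        x0=meta["xllcorner"] / scale,
        y0=meta["yllcorner"] / scale,
        cell=meta["cellsize"] / scale,
    )


def polygons_to_geojson(named_polys: dict[str, object], path: str | Path) -> None:
    """Write shapely polygons as a GeoJSON FeatureCollection keyed by id."""
    import shapely.geometry as sgeom

    feats = []
    for key, poly in named_polys.items():
        feats.append(
            {
                "type": "Feature",
                "properties": {"id": key},
                "geometry": sgeom.mapping(poly),
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def polygons_from_geojson(path: str | Path) -> dict[str, object]:
    import shapely.geometry as sgeom

    with open(path) as fh:
        gj = json.load(fh)
    return {
        f["properties"]["id"]: sgeom.shape(f["geometry"]) for f in gj["features"]
    }
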