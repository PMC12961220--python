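"""Triangulations for the SPDE spatial field.

The mesh follows the survey-extent heuristics: the inner-triangle maximum
edge is one-twelfth of the x-extent of the data (coarse mesh) or a fraction
of the estimated spatial range (fine mesh); the outer buffer extends the
triangulation by one-third of the x-extent to push boundary effects away
from the study area; the cutoff merges near-duplicate seed points.

Construction places seed nodes (cutoff-thinned data points, a hexagonal
fill lattice sized so Delaunay edges respect the max-edge bound, and a
sparse outer ring) and triangulates them with scipy's Delaunay.  The exact
node placement of any particular mesher is not replicated; the mesh is
validated through its contracts (max inner edge, containment, monotone
refinement) instead.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
from scipy.sparse import csr_matrix
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import Polygon

logger = logging.getLogger(__name__)

__all__ = [
    "MeshParams",
    "Mesh",
    "coarse_mesh_params",
    "fine_mesh_params",
    "build_mesh",
    "projection_matrix",
    "mesh_quality",
]

# hex-lattice spacing as a fraction of the max edge; sized so that the
# covering radius s/sqrt(3) keeps every Delaunay edge below the bound,
# with margin for irregularity where the lattice meets the boundary collar
_HEX_FACTOR = 0.78


@dataclass(frozen=True)
class MeshParams:
    """Mesh construction parameters, km."""

    max_edge_inner: float
    max_edge_outer: float
    offset_outer: float
    cutoff: float

    def __post_init__(self) -> None:
        for name in ("max_edge_inner", "max_edge_outer", "offset_outer", "cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.max_edge_outer < self.max_edge_inner:
            raise ValueError("max_edge_outer must be >= max_edge_inner")


def coarse_mesh_params(points: np.ndarray) -> MeshParams:
    """Survey-extent heuristic for the model-selection mesh.

    With ``extent_x = max(x) - min(x)``: inner max edge = extent_x / 12,
    outer offset = extent_x / 3, outer max edge = 5 x inner, cutoff =
    inner / 5.
    """
    points = np.atleast_2d(np.asarray(points, float))
    if points.shape[0] < 2:
        raise ValueError("need at least 2 points")
    extent_x = float(points[:, 0].max() - points[:, 0].min())
    if extent_x <= 0:
        raise ValueError("zero x-extent: cannot derive mesh parameters")
    inner = extent_x / 12.0
    return MeshParams(
        max_edge_inner=inner,
        max_edge_outer=5.0 * inner,
        offset_outer=extent_x / 3.0,
        cutoff=inner / 5.0,
    )


def fine_mesh_params(
    range_estimate: float,
    coarse: MeshParams,
    fraction: float = 1.0 / 10.0,
    cutoff_override: float | None = None,
) -> MeshParams:
    """Range-scaled refinement: inner max edge = fraction x posterior range.

    ``fraction`` is 1/10 for the fine mesh, 1/5 and 1/15 for the mesh
    sensitivity variants; ``cutoff_override`` (e.g. 0.5 km) supports the
    cutoff sensitivity analysis.  Other parameters inherit from the coarse
    heuristic.
    """
    if range_estimate <= 0:
        raise ValueError("range_estimate must be positive")
    if fraction <= 0:
        raise ValueError("fraction must be positive")
    inner = fraction * range_estimate
    cutoff = coarse.cutoff if cutoff_override is None else cutoff_override
    # an inherited coarse cutoff can exceed a small fine edge; clamp to the
    # edge/5 ratio so the mesh stays constructible
    if cutoff_override is None and cutoff >= inner:
        cutoff = inner / 5.0
    return MeshParams(
        max_edge_inner=inner,
        max_edge_outer=max(coarse.max_edge_outer, inner),
        offset_outer=coarse.offset_outer,
        cutoff=cutoff,
    )


@dataclass
class Mesh:
    """Triangulation with an inner (study-area) flag per triangle."""

    nodes: np.ndarray          # (n, 2)
    triangles: np.ndarray      # (m, 3) int
    inner: np.ndarray          # (m,) bool
    boundary: Polygon
    params: MeshParams | None = None

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    def triangle_areas(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        return 0.5 * np.abs(
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
        )

    def edge_lengths(self, inner_only: bool = False) -> np.ndarray:
        tris = self.triangles[self.inner] if inner_only else self.triangles
        e = np.vstack([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
        d = self.nodes[e[:, 0]] - self.nodes[e[:, 1]]
        return np.hypot(d[:, 0], d[:, 1])

    def to_json(self, path: str | Path) -> None:
        import shapely.geometry as sgeom

        rec = {
            "nodes": self.nodes.tolist(),
            "triangles": self.triangles.tolist(),
            "inner": self.inner.astype(int).tolist(),
            "boundary": sgeom.mapping(self.boundary),
            "params": None
            if self.params is None
            else {
                "max_edge_inner": self.params.max_edge_inner,
                "max_edge_outer": self.params.max_edge_outer,
                "offset_outer": self.params.offset_outer,
                "cutoff": self.params.cutoff,
            },
        }
        Path(path).write_text(json.dumps(rec))

    @classmethod
    def from_json(cls, path: str | Path) -> "Mesh":
        import shapely.geometry as sgeom

        rec = json.loads(Path(path).read_text())
        return cls(
            nodes=np.asarray(rec["nodes"], float),
            triangles=np.asarray(rec["triangles"], int),
            inner=np.asarray(rec["inner"], bool),
            boundary=sgeom.shape(rec["boundary"]),
            params=None if rec["params"] is None else MeshParams(**rec["params"]),
        )


def _thin_points(points: np.ndarray, cutoff: float) -> np.ndarray:
    """Greedy thinning in input order: keep a point only if at least
    ``cutoff`` away from every already-kept point (deterministic)."""
    kept: list[np.ndarray] = []
    tree = None
    for p in points:
        if tree is not None and tree.query(p, k=1)[0] < cutoff:
            continue
        kept.append(p)
        if len(kept) % 64 == 0 or tree is None:
            tree = cKDTree(np.asarray(kept))
        else:
            tree = cKDTree(np.asarray(kept))
    return np.asarray(kept) if kept else np.empty((0, 2))


def _hex_lattice(bounds: tuple[float, float, float, float], s: float) -> np.ndarray:
    xmin, ymin, xmax, ymax = bounds
    dy = s * np.sqrt(3.0) / 2.0
    rows = []
    n_rows = int(np.ceil((ymax - ymin) / dy)) + 2
    n_cols = int(np.ceil((xmax - xmin) / s)) + 2
    for j in range(n_rows):
        y = ymin + j * dy
        off = 0.5 * s if j % 2 else 0.0
        x = xmin + off + np.arange(n_cols) * s
        rows.append(np.column_stack([x, np.full(n_cols, y)]))
    pts = np.vstack(rows)
    keep = (pts[:, 0] <= xmax + s) & (pts[:, 1] <= ymax + dy)
    return pts[keep]


def _densify_ring(poly: Polygon, spacing: float) -> np.ndarray:
    ring = poly.exterior
    n = max(int(np.ceil(ring.length / spacing)), 4)
    return np.asarray(
        [ring.interpolate(i / n, normalized=True).coords[0] for i in range(n)]
    )


def build_mesh(points: np.ndarray, boundary: Polygon, params: MeshParams) -> Mesh:
    """Build the two-zone triangulation.

    Data points are cutoff-thinned and become mesh nodes; a hexagonal
    lattice at ``0.78 x max_edge_inner`` fills the study area (plus a small
    collar past the boundary so near-boundary triangles stay short); the
    buffer ring out to ``offset_outer`` is filled at the coarser outer
    spacing.  All nodes are Delaunay-triangulated and triangles are labeled
    inner when their centroid falls inside the study boundary.
    """
    if params.cutoff >= params.max_edge_inner:
        raise ValueError("cutoff must be smaller than max_edge_inner")
    points = np.atleast_2d(np.asarray(points, float))
    if boundary is None or boundary.is_empty or boundary.area <= 0:
        raise ValueError("invalid boundary polygon")

    data_nodes = _thin_points(points, params.cutoff)

    s_in = _HEX_FACTOR * params.max_edge_inner
    s_out = _HEX_FACTOR * params.max_edge_outer
    collar = boundary.buffer(1.2 * s_in)
    outer_poly = boundary.buffer(params.offset_outer)

    hex_in = _hex_lattice(collar.bounds, s_in)
    shapely.prepare(collar)
    hex_in = hex_in[shapely.covers(collar, shapely.points(hex_in))]

    hex_out = _hex_lattice(outer_poly.bounds, s_out)
    shapely.prepare(outer_poly)
    in_outer = shapely.covers(outer_poly, shapely.points(hex_out))
    in_collar = shapely.covers(collar, shapely.points(hex_out))
    hex_out = hex_out[in_outer & ~in_collar]
    ring = _densify_ring(outer_poly, s_out)

    nodes = np.vstack([data_nodes, hex_in, hex_out, ring])
    # drop exact near-duplicates (keeps the first occurrence: data first)
    tree = cKDTree(nodes)
    pairs = tree.query_pairs(1e-6 * s_in, output_type="ndarray")
    drop = np.zeros(len(nodes), dtype=bool)
    if len(pairs):
        drop[pairs.max(axis=1)] = True
    nodes = nodes[~drop]

    tri = Delaunay(nodes)
    simplices = tri.simplices
    p = nodes[simplices]
    areas = 0.5 * np.abs(
        (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
        - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
    )
    centroids = p.mean(axis=1)
    keep = areas > 1e-12 * s_in**2
    keep &= shapely.covers(outer_poly, shapely.points(centroids))
    simplices = simplices[keep]
    centroids = centroids[keep]

    shapely.prepare(boundary)
    inner = shapely.covers(boundary, shapely.points(centroids))

    mesh = Mesh(
        nodes=nodes,
        triangles=simplices,
        inner=inner,
        boundary=boundary,
        params=params,
    )
    logger.info(
        "build_mesh: %d nodes, %d triangles (%d inner)",
        mesh.n_nodes, mesh.n_triangles, int(inner.sum()),
    )
    return mesh


def projection_matrix(mesh: Mesh, locations: np.ndarray) -> csr_matrix:
    """Sparse barycentric interpolation matrix (locations x mesh nodes).

    Each in-mesh location row holds the barycentric weights of its
    containing triangle (at most 3 nonzeros summing to one); locations
    outside the mesh get an all-zero row and a warning.
    """
    locations = np.atleast_2d(np.asarray(locations, float))
    if locations.shape[0] == 0:
        raise ValueError("locations list is empty")
    tri_pts = mesh.nodes[mesh.triangles]
    # point-location via a fresh Delaunay of the mesh nodes would not honor
    # dropped triangles; use an STRtree over triangle polygons instead
    polys = shapely.polygons(tri_pts)
    tree = shapely.STRtree(polys)
    pts = shapely.points(locations)
    loc_idx, tri_idx = tree.query(pts, predicate="intersects")

    rows, cols, vals = [], [], []
    seen = np.zeros(locations.shape[0], dtype=bool)
    for li, ti in zip(loc_idx, tri_idx):
        if seen[li]:
            continue
        seen[li] = True
        a, b, c = tri_pts[ti]
        T = np.column_stack([b - a, c - a])
        try:
            lam = np.linalg.solve(T, locations[li] - a)
        except np.linalg.LinAlgError:
            continue
        w = np.array([1.0 - lam.sum(), lam[0], lam[1]])
        w = np.clip(w, 0.0, None)
        w /= w.sum()
        rows.extend([li] * 3)
        cols.extend(mesh.triangles[ti])
        vals.extend(w)
    n_out = int((~seen).sum())
    if n_out:
        logger.warning("projection_matrix: %d locations outside mesh", n_out)
    A = csr_matrix(
        (vals, (rows, cols)), shape=(locations.shape[0], mesh.n_nodes)
    )
    A.sum_duplicates()
    return A


def mesh_quality(mesh: Mesh) -> dict:
    """Min interior angle, inner max edge, edge histogram, node count."""
    p = mesh.nodes[mesh.triangles]
    angles = []
    for i in range(3):
        v1 = p[:, (i + 1) % 3] - p[:, i]
        v2 = p[:, (i + 2) % 3] - p[:, i]
        cosang = np.einsum("ij,ij->i", v1, v2) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
        )
        angles.append(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
    angles = np.column_stack(angles)
    edges = mesh.edge_lengths(inner_only=False)
    inner_edges = mesh.edge_lengths(inner_only=True)
    hist, hist_edges = np.histogram(edges, bins=20)
    return {
        "n_nodes": mesh.n_nodes,
        "n_triangles": mesh.n_triangles,
        "min_angle_deg": float(angles.min()),
        "max_edge": float(edges.max()),
        "inner_max_edge": float(inner_edges.max()) if inner_edges.size else np.nan,
        "edge_hist_counts": hist.tolist(),
        "edge_hist_bins": hist_edges.tolist(),
    }
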