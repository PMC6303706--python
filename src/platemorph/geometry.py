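"""Planar geometry primitives for plate outlines and sensilla point sets.

Polygons are ordered ``(n, 2)`` float arrays of vertices, implicitly closed
(the last vertex connects back to the first).  Area and centroid are the
usual polygon (shoelace / first-moment) quantities, delegated to shapely;
the centroid is the *area* centroid, not the vertex mean, so it is invariant
to how densely the outline was digitized.

The ``standardize_cloud`` transform rescales an outline to unit area and
translates its centroid to the origin, carrying the sensilla points along.
This makes point clouds from differently sized plates directly comparable
while preserving the relative positions of points within each plate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError, cKDTree
from shapely.geometry import LinearRing
from shapely.geometry import Polygon as _ShPolygon

__all__ = [
    "StandardizedCloud",
    "polygon_area",
    "polygon_centroid",
    "polygon_is_simple",
    "convex_hull",
    "nearest_neighbor_distances",
    "standardize_cloud",
]


def _as_points(p, name: str = "points") -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"{name} must be an (n, 2) array, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite coordinates")
    return arr


def _shapely_polygon(vertices: np.ndarray) -> _ShPolygon:
    poly = _ShPolygon(vertices)
    if poly.area == 0.0:
        raise ValueError("degenerate polygon: zero area (collinear vertices?)")
    return poly


def polygon_area(vertices) -> float:
    """Area of a simple polygon, independent of winding direction.

    Raises ``ValueError`` for degenerate (zero-area / collinear) input.
    """
    v = _as_points(vertices, "polygon")
    if len(v) < 3:
        raise ValueError("polygon needs >=3 vertices")
    return float(_shapely_polygon(v).area)


def polygon_centroid(vertices) -> np.ndarray:
    """Area-weighted centroid of a simple polygon (winding-invariant)."""
    v = _as_points(vertices, "polygon")
    if len(v) < 3:
        raise ValueError("polygon needs >=3 vertices")
    c = _shapely_polygon(v).centroid
    return np.array([c.x, c.y])


def polygon_is_simple(vertices) -> bool:
    """True when the closed outline does not self-intersect."""
    v = _as_points(vertices, "polygon")
    if len(v) < 3:
        return False
    try:
        return bool(LinearRing(v).is_simple)
    except Exception:
        return False


def convex_hull(points) -> np.ndarray:
    """Convex hull vertices, counterclockwise, collinear boundary points dropped.

    The vertex list is rotated so the lexicographically smallest vertex comes
    first, giving byte-stable output for identical input sets.
    """
    pts = _as_points(points)
    if len(pts) < 3:
        raise ValueError("convex hull needs >=3 points")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise ValueError(f"convex hull undefined (collinear points?): {exc}") from exc
    verts = pts[hull.vertices]  # Qhull returns CCW order in 2D
    start = np.lexsort((verts[:, 1], verts[:, 0]))[0]
    return np.roll(verts, -start, axis=0)


def nearest_neighbor_distances(points) -> np.ndarray:
    """Distance from each point to its closest other point, in input order.

    Duplicate points give distance 0 (with a warning).
    """
    pts = _as_points(points)
    if len(pts) < 2:
        raise ValueError("nearest-neighbor distances need >=2 points")
    tree = cKDTree(pts)
    dists, _ = tree.query(pts, k=2)
    out = dists[:, 1]
    if np.any(out == 0.0):
        warnings.warn("duplicate points yield zero nearest-neighbor distance")
    return out


@dataclass
class StandardizedCloud:
    """Sensilla coordinates after unit-area scaling and centroid translation.

    ``outline`` has area 1 and area-centroid (0, 0); ``points`` live in the
    same transformed frame, so pairwise distance *ratios* are unchanged.
    """

    outline: np.ndarray
    points: np.ndarray
    specimen_id: str | None = None
    scale: float = field(default=1.0)  # multiplicative factor that was applied

    def validate(self, tol: float = 1e-9) -> None:
        if abs(polygon_area(self.outline) - 1.0) > tol:
            raise ValueError("standardized outline area differs from 1")
        if np.linalg.norm(polygon_centroid(self.outline)) > tol:
            raise ValueError("standardized outline centroid differs from origin")


def standardize_cloud(outline, points, specimen_id: str | None = None) -> StandardizedCloud:
    """Scale outline (and points) to unit area, translate centroid to origin.

    Both the outline and the point set are scaled jointly by
    ``1/sqrt(area(outline))`` about the origin and then translated so the
    scaled outline's area centroid sits at ``(0, 0)``.  Applying the
    transform to an already standardized cloud is the identity.
    """
    out = _as_points(outline, "outline")
    pts = _as_points(points) if len(np.atleast_2d(points)) else np.empty((0, 2))
    area = polygon_area(out)
    s = 1.0 / np.sqrt(area)
    out_s = out * s
    pts_s = pts * s
    shift = polygon_centroid(out_s)
    return StandardizedCloud(
        outline=out_s - shift, points=pts_s - shift, specimen_id=specimen_id, scale=s
    )
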