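"""Convex-polygon helpers shared by the segmentation and geometry layers.

Pixels are treated as unit squares addressed by the (row, col) coordinates
of their centers.  A rasterized convex polygon contains every pixel whose
center lies inside or on the polygon; with that convention rasterization is
idempotent (re-hulling a rasterized hull reproduces it exactly).
"""
from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .errors import DegenerateInputError

_EDGE_TOL = 1e-9


def hull_of_points(points: np.ndarray) -> ConvexHull:
    """Convex hull of an (n, 2) array of (row, col) points.

    Raises
    ------
    DegenerateInputError
        For fewer than 3 points or collinear input.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or points.shape[0] < 3:
        raise DegenerateInputError("convex hull needs >=3 planar points")
    try:
        return ConvexHull(points)
    except QhullError as exc:  # collinear / degenerate
        raise DegenerateInputError(f"degenerate point set for convex hull: {exc}") from exc


def polygon_vertices(hull: ConvexHull) -> np.ndarray:
    """Hull vertices in traversal order, shape (k, 2)."""
    return hull.points[hull.vertices]


def contains(hull: ConvexHull, points: np.ndarray, tol: float = _EDGE_TOL) -> np.ndarray:
    """Boolean membership (inside or on boundary) for (m, 2) query points."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    # hull.equations rows are (a, b, c) with a*x + b*y + c <= 0 inside
    vals = points @ hull.equations[:, :2].T + hull.equations[:, 2]
    return np.all(vals <= tol, axis=1)


def rasterize_convex(hull: ConvexHull, shape: tuple[int, int]) -> np.ndarray:
    """Boolean raster of the hull on a grid of the given shape.

    A pixel is foreground iff its center satisfies every hull half-plane
    inequality (within a 1e-9 tolerance for boundary points).
    """
    nr, nc = shape
    lo = np.maximum(np.floor(hull.min_bound - 1).astype(int), 0)
    hi = np.minimum(np.ceil(hull.max_bound + 1).astype(int), [nr - 1, nc - 1])
    out = np.zeros(shape, dtype=bool)
    if np.any(hi < lo):
        return out
    rr, cc = np.mgrid[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1]
    pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    inside = contains(hull, pts)
    out[rr.ravel()[inside], cc.ravel()[inside]] = True
    return out


def rasterize_convex_points(points: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterized convex hull of arbitrary (row, col) points (vertices may be
    non-integer, e.g. after radial shrinkage)."""
    return rasterize_convex(hull_of_points(points), shape)


def clip_line_to_hull(hull: ConvexHull, origin: np.ndarray, direction: np.ndarray) -> tuple[float, float]:
    """Intersect the line ``origin + t * direction`` with the hull.

    Returns the parameter interval (t_min, t_max) of the chord.  Raises if
    the line misses the hull (cannot happen when origin is interior).
    """
    origin = np.asarray(origin, dtype=float)
    d = np.asarray(direction, dtype=float)
    a = hull.equations[:, :2]
    b = hull.equations[:, 2]
    denom = a @ d
    num = -(b + a @ origin)
    t_lo, t_hi = -np.inf, np.inf
    for de, nu in zip(denom, num):
        if abs(de) < 1e-12:
            if nu < -_EDGE_TOL:  # line parallel to and outside this facet
                raise DegenerateInputError("line does not intersect hull")
            continue
        t = nu / de
        if de > 0:
            t_hi = min(t_hi, t)
        else:
            t_lo = max(t_lo, t)
    if not (t_lo < t_hi):
        raise DegenerateInputError("line does not intersect hull")
    return float(t_lo), float(t_hi)


def polygon_perimeter_samples(vertices: np.ndarray, max_seg: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Densely resample a closed polygon boundary.

    Returns (midpoints, lengths) of small sub-segments no longer than
    ``max_seg`` pixels, suitable for accumulating arc length per angular
    sector with little discretization error.
    """
    vertices = np.asarray(vertices, dtype=float)
    mids, lens = [], []
    k = len(vertices)
    for i in range(k):
        p0, p1 = vertices[i], vertices[(i + 1) % k]
        seg = p1 - p0
        L = float(np.hypot(*seg))
        if L == 0:
            continue
        n = max(1, int(np.ceil(L / max_seg)))
        ts = (np.arange(n) + 0.5) / n
        mids.append(p0 + ts[:, None] * seg)
        lens.append(np.full(n, L / n))
    return np.concatenate(mids), np.concatenate(lens)


def point_to_polygon_distance(point: np.ndarray, vertices: np.ndarray) -> float:
    """Euclidean distance from a point to a closed polygon boundary."""
    p = np.asarray(point, dtype=float)
    v = np.asarray(vertices, dtype=float)
    w = np.roll(v, -1, axis=0)
    seg = w - v
    seg_len2 = np.einsum("ij,ij->i", seg, seg)
    t = np.clip(np.einsum("ij,ij->i", p - v, seg) / np.where(seg_len2 == 0, 1, seg_len2), 0, 1)
    proj = v + t[:, None] * seg
    return float(np.min(np.hypot(*(p - proj).T)))
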