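"""Chamber shape: PCA axes, SD-based aspect ratio, and P-A orientation.

The chamber outline is the convex hull of its nuclei.  PCA of the hull
interior pixel coordinates gives the major (posterior-anterior) and minor
axes; the aspect ratio is the ratio of the standard deviations of the
pixel coordinates projected on those axes.  SDs integrate over the whole
interior, so the ratio is far less sensitive to localized boundary defects
than a bounding-box length ratio would be — important for chambers
distorted during slide preparation.

PCA yields an axis, not a direction.  The anterior end is the side holding
the large nurse-cell nuclei, so we shrink the hull radially about the
centroid (losing the peripheral follicle-cell ring), split the interior
nuclei by the hyperplane through the centroid normal to the major axis,
and point the P-A direction at the half with more nuclei pixels.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DegenerateInputError
from .hullops import clip_line_to_hull, hull_of_points, rasterize_convex_points
from .image import BinaryMask
from .segmentation import NucleiSegmentation


@dataclass
class ChamberGeometry:
    centroid: np.ndarray          # (row, col) center of mass of hull interior
    major_axis: np.ndarray        # unit vector, (row, col)
    minor_axis: np.ndarray        # unit vector orthogonal to major_axis
    sd_major: float               # px
    sd_minor: float               # px
    ratio: float                  # sd_major / sd_minor >= 1
    pa_direction: np.ndarray | None = None   # ±major_axis, posterior → anterior
    flags: dict = field(default_factory=dict)

    @property
    def oriented(self) -> bool:
        return self.pa_direction is not None

    @property
    def normal_direction(self) -> np.ndarray:
        """Unit vector 90° counterclockwise from pa_direction (the 'dorsal'
        axis of the in-plane frame)."""
        d = self.pa_direction if self.oriented else self.major_axis
        return np.array([-d[1], d[0]])


@dataclass
class ShrunkenBoundary:
    mask: BinaryMask
    shrink_factor: float


@dataclass
class MiddleAxis:
    """Equally spaced sample points along the oriented P-A chord.

    ``points[0]`` is the posterior-most point; ``offsets[i]`` is the signed
    position of ``points[i]`` along ``pa_direction`` relative to the
    centroid, so ``offsets`` is strictly increasing.
    """

    points: np.ndarray    # (n, 2) coordinates Q1..Qn, posterior first
    offsets: np.ndarray   # (n,) signed positions along pa_direction
    spacing: float        # px between consecutive points


def pca_axes(hull: NucleiSegmentation) -> ChamberGeometry:
    """Principal axes and SD ratio of the hull-interior pixel cloud."""
    coords = np.argwhere(hull.hull_mask.pixels).astype(float)
    if len(coords) < 3:
        raise DegenerateInputError("hull has fewer than 3 pixels")
    centroid = coords.mean(axis=0)
    cov = np.cov((coords - centroid).T)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[0] <= 0:
        raise DegenerateInputError("degenerate (collinear) hull interior")
    flags = {}
    if (evals[1] - evals[0]) / evals[1] < 1e-9:
        # isotropic shape: axes are arbitrary; fall back to image axes
        evecs = np.eye(2)
        flags["isotropic"] = True
    sd_minor, sd_major = float(np.sqrt(evals[0])), float(np.sqrt(evals[1]))
    return ChamberGeometry(
        centroid=centroid,
        major_axis=evecs[:, 1],
        minor_axis=evecs[:, 0],
        sd_major=sd_major,
        sd_minor=sd_minor,
        ratio=sd_major / sd_minor,
        flags=flags,
    )


def shrink_boundary(hull: NucleiSegmentation, shrink_factor: float) -> ShrunkenBoundary:
    """Scale the hull polygon radially about the centroid by ``shrink_factor``.

    Small somatic follicle-cell nuclei form a thin peripheral band at every
    stage, so a modest radial shrink leaves them (and only them) outside.
    """
    if not (0 < shrink_factor < 1):
        raise ValueError(f"shrink_factor must be in (0, 1), got {shrink_factor}")
    coords = np.argwhere(hull.hull_mask.pixels).astype(float)
    centroid = coords.mean(axis=0)
    verts = centroid + shrink_factor * (hull.hull_vertices - centroid)
    mask_px = rasterize_convex_points(verts, hull.hull_mask.shape)
    if mask_px.sum() < 3:
        raise DegenerateInputError("shrunken boundary collapsed below 3 pixels")
    mask_px &= hull.hull_mask.pixels  # rasterization guard: stay inside hull
    return ShrunkenBoundary(mask=BinaryMask(mask_px, provenance="shrink_boundary"),
                            shrink_factor=shrink_factor)


def orient_pa_axis(nuclei: BinaryMask, geom: ChamberGeometry,
                   shrunk: ShrunkenBoundary) -> ChamberGeometry:
    """Orient the major axis posterior → anterior by nurse-cell asymmetry.

    Nuclei surviving inside the shrunken boundary are (pieces of) the large
    nurse cells.  Counting their pixels on each side of the centroid is
    robust to touching nuclei, which defeat per-cell instance counting.
    """
    interior = nuclei.pixels & shrunk.mask.pixels
    coords = np.argwhere(interior).astype(float)
    flags = dict(geom.flags)
    if len(coords) == 0:
        flags["orientation_tie"] = True
        return replace(geom, pa_direction=geom.major_axis.copy(), flags=flags)
    proj = (coords - geom.centroid) @ geom.major_axis
    n_pos = int(np.sum(proj > 0))
    n_neg = int(np.sum(proj < 0))
    if n_pos == n_neg:
        flags["orientation_tie"] = True
        pa = geom.major_axis.copy()
    elif n_pos > n_neg:
        pa = geom.major_axis.copy()      # anterior on the +major side
    else:
        pa = -geom.major_axis
    return replace(geom, pa_direction=pa, flags=flags)


def middle_axis(geom: ChamberGeometry, hull: NucleiSegmentation,
                n_points: int = 30) -> MiddleAxis:
    """Sample the P-A chord through the centroid at ``n_points`` equally
    spaced positions, posterior end first."""
    if not geom.oriented:
        raise DegenerateInputError("middle_axis requires an oriented geometry")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    hull_geom = hull_of_points(np.argwhere(hull.hull_mask.pixels).astype(float))
    t_min, t_max = clip_line_to_hull(hull_geom, geom.centroid, geom.pa_direction)
    offsets = np.linspace(t_min, t_max, n_points)
    points = geom.centroid + offsets[:, None] * geom.pa_direction
    return MiddleAxis(points=points, offsets=offsets,
                      spacing=float((t_max - t_min) / (n_points - 1)))
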