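"""Per-chamber scalar features: oocyte size and follicle-cell uniformity.

Oocyte size — the oocyte nucleus region is DAPI-sparse, so the posterior of
the chamber appears dark from stage 6 on.  We scan 30 bands perpendicular
to the P-A axis from the posterior end and place the oocyte boundary at the
first band whose nuclei-pixel fraction reaches 10%; everything posterior of
that line is oocyte.

Follicle-cell distribution — after radial shrinkage only follicle cells lie
entirely outside the shrunken boundary.  Their pixels are binned into 12
equal-angle sectors about the centroid (sector 1 starting at the anterior
end), each count divided by the chamber-boundary arc length in the sector.
The Δ-distance of the normalized 12-vector to the uniform distribution is a
single uniformity score: anterior follicle cells stretch apart at stage 9,
which pushes the score up — the basis of the stage-8/9 rule.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError
from .geometry import ChamberGeometry, MiddleAxis, ShrunkenBoundary
from .hullops import polygon_perimeter_samples
from .image import BinaryMask
from .segmentation import CONN8, NucleiSegmentation


@dataclass
class OocyteEstimate:
    boundary_index: int | None    # 1-based index of the axis point Q_i
    area_fraction: float          # oocyte px / chamber px
    axis_fraction: float          # oocyte axis length / whole axis length
    found: bool
    boundary_offset: float | None = None  # signed position along pa_direction


@dataclass
class SectorDistribution:
    densities: np.ndarray         # per-sector follicle px / boundary px
    normalized: np.ndarray        # densities scaled to sum to 1
    delta_to_uniform: float
    counts: np.ndarray = field(default=None)        # raw follicle px per sector
    boundary_lengths: np.ndarray = field(default=None)


def _hull_projections(hull: NucleiSegmentation, geom: ChamberGeometry):
    coords = np.argwhere(hull.hull_mask.pixels).astype(float)
    return coords, (coords - geom.centroid) @ geom.pa_direction


def oocyte_boundary(nuclei: BinaryMask, axis: MiddleAxis, geom: ChamberGeometry,
                    hull: NucleiSegmentation, frac_threshold: float = 0.10) -> OocyteEstimate:
    """Locate the oocyte boundary along the middle axis.

    ``nuclei`` should be the interior-cell (nurse) mask, with the
    peripheral follicle ring already removed: the ring wraps the posterior
    pole too, so counting it would mark even the DAPI-sparse oocyte bands
    as occupied.

    Bands are half-open intervals [Q_i, Q_{i+1}) of the signed position
    along the P-A direction, so they partition the hull.  The band fraction
    is nuclei pixels over total pixels in the band.  When no band reaches
    the threshold the oocyte is undefined — legitimate for early stages —
    and both fractions are reported as 0 with ``found=False``.
    """
    if not geom.oriented:
        raise DegenerateInputError("oocyte_boundary requires oriented geometry")
    coords, s = _hull_projections(hull, geom)
    nuc = nuclei.pixels[tuple(coords.astype(int).T)]
    offs = axis.offsets
    boundary_index = None
    for i in range(len(offs) - 1):
        in_band = (s >= offs[i]) & (s < offs[i + 1])
        total = int(in_band.sum())
        if total == 0:
            continue
        frac = float(nuc[in_band].sum()) / total
        if frac >= frac_threshold:
            boundary_index = i + 1  # 1-based Q index
            break
    if boundary_index is None:
        return OocyteEstimate(None, 0.0, 0.0, found=False)
    t_b = float(offs[boundary_index - 1])
    area_fraction = float(np.sum(s < t_b)) / len(s)
    axis_fraction = (t_b - offs[0]) / (offs[-1] - offs[0])
    return OocyteEstimate(boundary_index, area_fraction, float(axis_fraction),
                          found=True, boundary_offset=t_b)


def area_quantile_lines(hull: NucleiSegmentation, geom: ChamberGeometry,
                        fractions: list[float]) -> list[float]:
    """Signed positions along the P-A direction whose posterior half-plane
    holds the requested fraction of chamber area (used for the 1/3, 1/2,
    2/3 visualization lines)."""
    if any(not (0 < f < 1) for f in fractions):
        raise ValueError("fractions must lie in (0, 1)")
    _, s = _hull_projections(hull, geom)
    return [float(np.quantile(s, f)) for f in fractions]


def separate_follicle_cells(nuclei: BinaryMask, shrunk: ShrunkenBoundary) -> BinaryMask:
    """Keep nuclei components lying entirely outside the shrunken boundary.

    Nurse cells are much larger than follicle cells, so any component that
    touches the shrunken interior is a nurse cell and is dropped whole.
    """
    labels, n = ndimage.label(nuclei.pixels, structure=CONN8)
    if n == 0:
        out = BinaryMask(np.zeros_like(nuclei.pixels), provenance="separate_follicle_cells")
        out.flags["empty"] = True
        return out
    inside = np.unique(labels[shrunk.mask.pixels])
    keep = np.ones(n + 1, dtype=bool)
    keep[0] = False
    keep[inside[inside > 0]] = False
    out = BinaryMask(keep[labels], provenance="separate_follicle_cells")
    if not out.pixels.any():
        out.flags["empty"] = True
    return out


def interior_cells(nuclei: BinaryMask, shrunk: ShrunkenBoundary) -> BinaryMask:
    """Complement of :func:`separate_follicle_cells`: nuclei components that
    reach into the shrunken boundary — the nurse cells (and, late, any
    centripetally migrating cells attached to them)."""
    follicle = separate_follicle_cells(nuclei, shrunk)
    return BinaryMask(nuclei.pixels & ~follicle.pixels, provenance="interior_cells")


def delta_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Δ-distance between two discrete distributions.

    Triangular discrimination Δ(p, q) = Σ_i (p_i − q_i)² / (p_i + q_i),
    with 0/0 terms contributing 0.  Symmetric, zero iff p = q, and bounded
    above by 2 (attained by distributions with disjoint support).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q must have the same length")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("distributions must be non-negative")
    for name, v in (("p", p), ("q", q)):
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError(f"{name} must sum to 1 (got {v.sum()})")
    denom = p + q
    num = (p - q) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return float(terms.sum())


def sector_densities(follicle: BinaryMask, geom: ChamberGeometry,
                     hull: NucleiSegmentation, n_sectors: int = 12) -> SectorDistribution:
    """Follicle-cell density in equal-angle sectors about the centroid.

    The frame is (P-A direction, its 90° CCW normal); sector 1 opens at the
    anterior tip and sectors proceed counterclockwise.  Density divides the
    follicle pixel count by the hull-boundary arc length inside the sector
    (polyline length on the hull polygon — less rasterization noise than
    counting perimeter pixels).
    """
    if not geom.oriented:
        raise DegenerateInputError("sector_densities requires oriented geometry")
    if not follicle.pixels.any():
        raise DegenerateInputError("empty follicle mask: distribution undefined")
    u = geom.pa_direction
    v = geom.normal_direction
    width = 2 * np.pi / n_sectors

    def sector_of(points: np.ndarray) -> np.ndarray:
        rel = points - geom.centroid
        theta = np.arctan2(rel @ v, rel @ u) % (2 * np.pi)
        return np.minimum((theta // width).astype(int), n_sectors - 1)

    counts = np.bincount(sector_of(np.argwhere(follicle.pixels).astype(float)),
                         minlength=n_sectors).astype(float)
    mids, lens = polygon_perimeter_samples(hull.hull_vertices)
    lengths = np.zeros(n_sectors)
    np.add.at(lengths, sector_of(mids), lens)
    if (lengths <= 0).any():
        raise DegenerateInputError("sector with zero boundary length")
    densities = counts / lengths
    normalized = densities / densities.sum()
    uniform = np.full(n_sectors, 1.0 / n_sectors)
    return SectorDistribution(
        densities=densities,
        normalized=normalized,
        delta_to_uniform=delta_distance(normalized, uniform),
        counts=counts,
        boundary_lengths=lengths,
    )
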