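"""Stage-specific detectors.

Polytene blob detection (stage 4) — at stage 4 the polytene chromosomes of
nurse-cell nuclei condense into several discrete blobs.  A marker-controlled
watershed on each nucleus's intensity relief splits the nucleus into one
catchment basin per blob; a median fragment count of 3 or more across
nuclei flags the chamber as blob-positive.

Centripetal migration (stage 10B) — at stage 10B follicle cells migrate
inward along the nurse-cell/oocyte boundary.  A band of width 0.8 × the
major-axis SD is anchored at the detected oocyte boundary; small nuclei
lying *entirely* inside the band (nurse cells only straddle it) and close
to the chamber rim are reported as centripetal cells, the 10A/10B
discriminator.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import sobel
from skimage.morphology import disk, local_maxima
from skimage.segmentation import watershed

from .errors import DegenerateInputError
from .features import OocyteEstimate
from .geometry import ChamberGeometry
from .hullops import point_to_polygon_distance
from .image import BinaryMask, ChamberImage
from .segmentation import CONN8, NucleiSegmentation


@dataclass
class PolyteneResult:
    nucleus_labels: np.ndarray        # labeled nurse-cell nuclei
    fragment_labels: np.ndarray       # watershed sub-regions (global labels)
    fragments_per_nucleus: np.ndarray
    median_fragments: float
    is_blob_positive: bool


@dataclass
class CentripetalResult:
    band_mask: BinaryMask
    candidate_labels: list[int]
    centripetal_labels: list[int]
    cell_labels: np.ndarray           # labeling of the input nuclei mask
    is_stage_10B: bool
    applicable: bool


def detect_polytene(nurse_image: ChamberImage, nurse_mask: BinaryMask,
                    median_threshold: float = 3.0,
                    marker_rel_height: float = 0.5,
                    opening_radius: int = 2) -> PolyteneResult:
    """Count watershed fragments per nurse-cell nucleus.

    Markers are the regional maxima of the intensity image after grayscale
    opening with a small disk (suppressing single-pixel peaks); the
    watershed floods the intensity-gradient relief within each nucleus.
    Maxima dimmer than ``marker_rel_height`` of the nucleus peak are not
    trusted as chromosome blobs.
    """
    if not nurse_mask.pixels.any():
        raise DegenerateInputError("empty nurse mask")
    img = nurse_image.normalized().pixels
    labels, n = ndimage.label(nurse_mask.pixels, structure=CONN8)
    opened = ndimage.grey_opening(img, footprint=disk(opening_radius))
    fragment_labels = np.zeros_like(labels)
    counts = np.zeros(n, dtype=int)
    next_label = 1
    slices = ndimage.find_objects(labels)
    for i, sl in enumerate(slices, start=1):
        comp = labels[sl] == i
        sub_open = np.where(comp, opened[sl], 0.0)
        maxima = local_maxima(sub_open, connectivity=2) & comp
        maxima &= sub_open >= marker_rel_height * sub_open.max()
        markers, n_mark = ndimage.label(maxima, structure=CONN8)
        if n_mark == 0:  # flat nucleus: single catchment basin
            fragment_labels[sl][comp] = next_label
            counts[i - 1] = 1
            next_label += 1
            continue
        grad = sobel(np.where(comp, img[sl], 0.0))
        ws = watershed(grad, markers=markers, mask=comp)
        fragment_labels[sl][comp] = ws[comp] + (next_label - 1)
        counts[i - 1] = n_mark
        next_label += n_mark
    median = float(np.median(counts))
    return PolyteneResult(
        nucleus_labels=labels,
        fragment_labels=fragment_labels,
        fragments_per_nucleus=counts,
        median_fragments=median,
        is_blob_positive=median >= median_threshold,
    )


def detect_centripetal(nuclei: BinaryMask, geom: ChamberGeometry,
                       oocyte: OocyteEstimate, hull: NucleiSegmentation,
                       bandwidth_sds: float = 0.8,
                       rim_proximity_sds: float = 0.15,
                       min_cells: int = 2) -> CentripetalResult:
    """Find whole cells inside the oocyte-boundary band near the rim.

    The band is centered on the oocyte boundary, has total width
    ``bandwidth_sds × sd_major``, and runs perpendicular to the P-A axis —
    wide enough to capture all migrating cells, narrow enough that no
    entire nurse cell fits inside.  Candidates must lie entirely within the
    band; centripetal cells are candidates whose centroid is within
    ``rim_proximity_sds × sd_minor`` of the hull boundary.
    """
    empty = BinaryMask(np.zeros_like(nuclei.pixels), provenance="detect_centripetal")
    if not (oocyte.found and geom.oriented):
        return CentripetalResult(empty, [], [], np.zeros_like(nuclei.pixels, dtype=int),
                                 is_stage_10B=False, applicable=False)
    half_w = 0.5 * bandwidth_sds * geom.sd_major
    lo, hi = oocyte.boundary_offset - half_w, oocyte.boundary_offset + half_w

    coords_hull = np.argwhere(hull.hull_mask.pixels).astype(float)
    s_hull = (coords_hull - geom.centroid) @ geom.pa_direction
    band_px = np.zeros_like(nuclei.pixels)
    in_band = (s_hull >= lo) & (s_hull <= hi)
    band_px[tuple(coords_hull[in_band].astype(int).T)] = True
    band = BinaryMask(band_px, provenance="detect_centripetal")

    labels, n = ndimage.label(nuclei.pixels, structure=CONN8)
    candidates, centripetal = [], []
    rim_tol = rim_proximity_sds * geom.sd_minor
    for i in range(1, n + 1):
        coords = np.argwhere(labels == i).astype(float)
        s = (coords - geom.centroid) @ geom.pa_direction
        if s.min() < lo or s.max() > hi:
            continue  # only partially in the band (or outside): excluded
        candidates.append(i)
        centroid = coords.mean(axis=0)
        if point_to_polygon_distance(centroid, hull.hull_vertices) <= rim_tol:
            centripetal.append(i)
    return CentripetalResult(
        band_mask=band,
        candidate_labels=candidates,
        centripetal_labels=centripetal,
        cell_labels=labels,
        is_stage_10B=len(centripetal) >= min_cells,
        applicable=True,
    )
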