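"""Egg-chamber segmentation from a single-plane DAPI image.

The chamber is isolated in five steps: (1) binarize at a fraction of Otsu's
threshold so even dim nuclei survive, (2) blur the binary image with an
average filter and re-binarize so the chamber's nuclei fuse into one
connected region while sparse noise stays fragmented, (3) keep the largest
connected component and fill its holes to obtain a chamber mask, (4) run
Chan-Vese active contours on the masked intensities to segment individual
nuclei, and (5) take the convex hull of the nuclei as the chamber outline;
its pixel count times the pixel area gives chamber size in μm².
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.segmentation import chan_vese as _sk_chan_vese

from .errors import DegenerateInputError, SegmentationError
from .hullops import hull_of_points, polygon_vertices, rasterize_convex
from .image import BinaryMask, ChamberImage

#: 8-connectivity structuring element used for all component labelling.
CONN8 = np.ones((3, 3), dtype=bool)


@dataclass
class ChanVeseParams:
    """Chan-Vese energy weights and initialization.

    ``mu`` penalizes boundary length; ``lambda1``/``lambda2`` weight the
    intensity-fidelity terms of foreground and background.  The contour is
    initialized as a regular grid of small circles (many disjoint loops), a
    natural seed when the target foreground is a field of compact nuclei.
    """

    mu: float = 0.25
    lambda1: float = 1.0
    lambda2: float = 1.0
    max_iter: int = 200
    tol: float = 1e-3
    init_circle_radius: float = 3.0
    init_circle_spacing: float = 8.0


@dataclass
class SegmentationConfig:
    """Pipeline settings.

    ``filter_window`` may be given directly in pixels; when None it is
    derived from ``filter_window_um`` and the image calibration, so the
    blur bridges the same physical inter-nucleus gaps at any
    magnification.
    """

    otsu_scale: float = 0.2
    filter_window: int | None = None
    filter_window_um: float = 15.0
    chan_vese: ChanVeseParams = field(default_factory=ChanVeseParams)

    def window_for(self, pixel_size: float) -> int:
        if self.filter_window is not None:
            return self.filter_window
        w = int(round(self.filter_window_um / pixel_size))
        w = max(5, min(w, 31))
        return w if w % 2 == 1 else w + 1


@dataclass
class NucleiSegmentation:
    """Final product of the pipeline: nuclei, their convex hull, and area."""

    nuclei_mask: BinaryMask
    hull_mask: BinaryMask
    hull_area: float  # μm²
    hull_vertices: np.ndarray  # (k, 2) hull boundary polygon, (row, col)
    pixel_size: float


def scaled_otsu_binarize(image: ChamberImage, scale: float = 0.2) -> BinaryMask:
    """Threshold at ``scale`` × Otsu's threshold of the full histogram.

    The deliberately low default (0.2) keeps every desired foreground
    object: DAPI nuclei vary widely in brightness and a plain Otsu cut
    loses the dim ones.
    """
    if not (0 < scale <= 1):
        raise ValueError(f"scale must be in (0, 1], got {scale}")
    px = image.normalized().pixels
    if px.max() == px.min():
        raise DegenerateInputError("constant image: Otsu threshold undefined")
    t = threshold_otsu(px, nbins=256)
    return BinaryMask(px > scale * t, provenance="scaled_otsu_binarize")


def average_filter(mask: BinaryMask, window: int = 15) -> ChamberImage:
    """Mean filter over a ``window``×``window`` neighborhood (replicate
    padding at the borders), mapping the binary raster to grayscale [0, 1]."""
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    out = ndimage.uniform_filter(mask.pixels.astype(np.float64), size=window, mode="nearest")
    # uniform_filter is numerically exact enough, but clip guard keeps [0,1]
    return ChamberImage(np.clip(out, 0.0, 1.0), pixel_size=1.0)


def largest_component(mask: BinaryMask) -> BinaryMask:
    """Keep only the largest 8-connected foreground component.

    Ties are broken in favor of the component first encountered in
    raster-scan order (the smallest label).
    """
    labels, n = ndimage.label(mask.pixels, structure=CONN8)
    if n == 0:
        raise SegmentationError("largest_component", "empty mask: no foreground")
    sizes = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(sizes)) + 1  # argmax returns first max -> smallest label
    return BinaryMask(labels == best, provenance="largest_component")


def fill_and_apply_mask(mask: BinaryMask, image: ChamberImage) -> ChamberImage:
    """Fill holes in ``mask`` and use it to gate the original intensities."""
    if mask.shape != image.shape:
        raise ValueError("mask and image shapes differ")
    filled = ndimage.binary_fill_holes(mask.pixels)
    return ChamberImage(np.where(filled, image.pixels, 0.0), image.pixel_size)


def _circle_grid_level_set(shape: tuple[int, int], radius: float, spacing: float) -> np.ndarray:
    """Initial level set: positive inside a regular grid of small circles."""
    nr, nc = shape
    r0 = np.arange(spacing / 2, nr, spacing)
    c0 = np.arange(spacing / 2, nc, spacing)
    rr, cc = np.mgrid[0:nr, 0:nc]
    dr = np.min(np.abs(rr[..., None] - r0[None, None, :]), axis=-1)
    dc = np.min(np.abs(cc[..., None] - c0[None, None, :]), axis=-1)
    # distance to the nearest grid node; circles of the given radius
    return radius - np.hypot(dr, dc)


def chan_vese_nuclei(image: ChamberImage, params: ChanVeseParams | None = None,
                     init_restrict: np.ndarray | None = None) -> BinaryMask:
    """Segment nuclei with the Chan-Vese active contour.

    The model splits the image into two regions of near-constant intensity
    by minimizing boundary length plus within-region intensity variance,
    so the result depends only on intensity contrasts (it is invariant to
    adding a constant).  Initialization is a fixed grid of small circles —
    there is no hidden randomness and repeated runs are bit-identical.

    Grid circles are kept only over a candidate-foreground region
    (``init_restrict``; by default pixels above the Otsu threshold)
    and start collapsed elsewhere.  Seeding bright and dark regions alike
    makes the two region means start equal, and the contour can collapse
    to nothing before they separate; seeding on candidate nuclei avoids
    that, and also prevents stray loops from surviving in large flat dark
    areas such as the oocyte.

    A degenerate (empty or full) foreground is returned with
    ``flags['degenerate'] = True`` rather than raised: it is the honest
    answer for a contrast-free image.
    """
    params = params or ChanVeseParams()
    px = image.normalized().pixels
    if px.max() == px.min():
        out = BinaryMask(np.zeros_like(px, dtype=bool), provenance="chan_vese_nuclei")
        out.flags["degenerate"] = True
        return out
    if init_restrict is None:
        init_restrict = px > threshold_otsu(px, nbins=256)
    init = _circle_grid_level_set(px.shape, params.init_circle_radius, params.init_circle_spacing)
    init = np.where(init_restrict, init, -params.init_circle_radius)
    seg = _sk_chan_vese(
        px,
        mu=params.mu,
        lambda1=params.lambda1,
        lambda2=params.lambda2,
        tol=params.tol,
        max_num_iter=params.max_iter,
        dt=0.5,
        init_level_set=init,
    )
    # chan_vese labels the phi>0 region as "foreground"; ensure foreground is
    # the brighter region (nuclei are bright on dark background)
    if seg.any() and (~seg).any():
        if px[seg].mean() < px[~seg].mean():
            seg = ~seg
    mask = BinaryMask(seg, provenance="chan_vese_nuclei")
    if not seg.any() or seg.all():
        mask.flags["degenerate"] = True
    return mask


def hull_and_area(nuclei: BinaryMask, pixel_size: float) -> NucleiSegmentation:
    """Convex hull of the nuclei pixels; hull pixel count × pixel area = μm².

    The hull is rasterized with a center-in-polygon rule, which makes the
    operation idempotent: the hull mask is its own convex hull.
    """
    pts = np.argwhere(nuclei.pixels)
    if len(pts) < 3:
        raise DegenerateInputError("need >=3 nuclei pixels for a convex hull")
    hull = hull_of_points(pts)  # raises on collinear input
    hull_px = rasterize_convex(hull, nuclei.shape)
    hull_px |= nuclei.pixels  # guard: every nucleus pixel belongs to its hull
    return NucleiSegmentation(
        nuclei_mask=nuclei,
        hull_mask=BinaryMask(hull_px, provenance="hull_and_area"),
        hull_area=float(hull_px.sum()) * pixel_size**2,
        hull_vertices=polygon_vertices(hull),
        pixel_size=pixel_size,
    )


@dataclass
class SegmentationResult:
    """Final segmentation plus every intermediate for audit/visualization."""

    segmentation: NucleiSegmentation
    intermediates: dict


def segment_chamber(image: ChamberImage, config: SegmentationConfig | None = None) -> SegmentationResult:
    """Run the full chamber-isolation pipeline on one cropped DAPI image."""
    config = config or SegmentationConfig()
    inter: dict = {}
    try:
        stage = "scaled_otsu_binarize"
        norm = image.normalized()
        inter["normalized"] = norm
        raw_mask = scaled_otsu_binarize(norm, config.otsu_scale)
        inter["binary_initial"] = raw_mask

        stage = "average_filter"
        blurred = average_filter(raw_mask, config.window_for(image.pixel_size))
        inter["filtered"] = blurred

        stage = "rebinarize"
        t = threshold_otsu(blurred.pixels, nbins=256)
        rebin = BinaryMask(blurred.pixels > t, provenance="rebinarize")
        inter["binary_filtered"] = rebin

        stage = "largest_component"
        largest = largest_component(rebin)
        inter["largest_component"] = largest

        stage = "fill_and_apply_mask"
        denoised = fill_and_apply_mask(largest, norm)
        inter["denoised"] = denoised

        stage = "chan_vese_nuclei"
        # seed the contour only on candidate nuclei: initial-threshold
        # foreground within the chamber region.  The contour is run on the
        # chamber bounding box only — everything outside is already zero.
        filled = ndimage.binary_fill_holes(largest.pixels)
        restrict = raw_mask.pixels & filled
        rows = np.any(filled, axis=1)
        cols = np.any(filled, axis=0)
        r0, r1 = np.argmax(rows), len(rows) - np.argmax(rows[::-1])
        c0, c1 = np.argmax(cols), len(cols) - np.argmax(cols[::-1])
        pad = 4
        r0, c0 = max(0, r0 - pad), max(0, c0 - pad)
        r1, c1 = min(filled.shape[0], r1 + pad), min(filled.shape[1], c1 + pad)
        crop = ChamberImage(denoised.pixels[r0:r1, c0:c1], denoised.pixel_size)
        nuc_crop = chan_vese_nuclei(crop, config.chan_vese,
                                    init_restrict=restrict[r0:r1, c0:c1])
        nuc_px = np.zeros(denoised.shape, dtype=bool)
        nuc_px[r0:r1, c0:c1] = nuc_crop.pixels
        nuclei = BinaryMask(nuc_px, provenance="chan_vese_nuclei", flags=nuc_crop.flags)
        # restrict to the chamber region: the active contour may keep faint
        # off-chamber residue that the mask already excluded
        nuclei = BinaryMask(nuclei.pixels & (denoised.pixels > 0), provenance="chan_vese_nuclei",
                            flags=nuclei.flags)
        inter["nuclei"] = nuclei

        stage = "hull_and_area"
        seg = hull_and_area(nuclei, image.pixel_size)
    except (DegenerateInputError, ValueError) as exc:
        raise SegmentationError(stage, str(exc)) from exc
    return SegmentationResult(segmentation=seg, intermediates=inter)
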