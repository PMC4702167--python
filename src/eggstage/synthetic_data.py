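"""Synthetic DAPI-like egg chambers with known ground truth.

No public image set exists for this pipeline, so testing rests on a
renderer that emulates what a midsagittal DAPI section actually shows:

* an elliptical chamber whose log-area grows linearly with stage
  (exponential growth at constant rate) and whose aspect ratio drifts from
  ~1 toward ~3;
* a thin peripheral ring of small, bright follicle-cell nuclei, optionally
  thinned near the anterior pole (the stage-9 stretching signature);
* large nurse-cell nuclei filling the anterior interior, rendered either
  as smooth single-peak profiles or as multi-blob "polytene" textures
  (the stage-4 signature);
* a DAPI-sparse posterior oocyte region from stage 6 on;
* optional centripetal cells inside the nurse/oocyte boundary band (10B);
* background noise and off-chamber distractor blobs.

Nuclei carry Gaussian intensity profiles (realistic DAPI falloff) so the
active-contour step faces a genuine boundary-finding task.  Every random
choice flows from the seed in the spec; the same spec renders the same
raster bit for bit.

``generate_feature_table`` draws per-stage feature vectors directly from
the same growth model, for statistics tests that do not need images.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import DegenerateInputError
from .hullops import rasterize_convex_points
from .image import BinaryMask, ChamberImage

#: default exponential growth model: log-area (μm²) linear in stage
GROWTH_SLOPE = 0.38          # per stage
GROWTH_INTERCEPT = np.log(1500.0)   # log μm² at stage 2
GROWTH_NOISE = 0.15          # SD of log-area about the line

RATIO_SLOPE = 0.2            # aspect ratio drifts 1 -> 3 over stages 2..12
RATIO_NOISE = 0.25
OOCYTE_NOISE = 0.04
DELTA_EARLY = (0.12, 0.05)   # Δ-distance mean/SD through stage 8
DELTA_LATE = (0.30, 0.05)    # from stage 9 on

DEFAULT_PIXEL_SIZE = 1.6     # μm per pixel for rendered images


def _ratio_for_stage(stage: int) -> float:
    return 1.0 + RATIO_SLOPE * (stage - 2)


def _oocyte_fraction_for_stage(stage: int) -> float:
    """Oocyte fraction: 0 before stage 6, then growing, accelerating after
    stage 10 when nurse-cell dumping begins."""
    if stage < 6:
        return 0.0
    f = 0.15 + 0.05 * (stage - 6) + 0.12 * max(0, stage - 10) ** 1.5
    return min(f, 0.9)


@dataclass
class NoiseSpec:
    background_sd: float = 0.02
    n_distractors: int = 3
    distractor_amplitude: float = 0.7


@dataclass
class ChamberSpec:
    """Everything needed to render one chamber deterministically."""

    stage: int
    axes: tuple[float, float]            # (semi-major, semi-minor) px
    ratio: float
    n_follicle: int
    follicle_uniformity: float = 0.0     # 0 = uniform ring, ~0.6 = stage-9 thinning
    oocyte_fraction: float = 0.0
    nurse_texture: str = "smooth"        # or "blobby"
    n_nurse: int = 7
    centripetal: bool = False
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    pixel_size: float = DEFAULT_PIXEL_SIZE
    seed: int = 0

    def __post_init__(self):
        if self.ratio < 1:
            raise ValueError("ratio must be >= 1")
        if not (0 <= self.oocyte_fraction <= 0.9):
            raise ValueError("oocyte_fraction must be in [0, 0.9]")
        if self.n_follicle < 0 or self.n_nurse < 0:
            raise ValueError("counts must be >= 0")
        if self.nurse_texture not in ("smooth", "blobby"):
            raise ValueError(f"unknown nurse_texture {self.nurse_texture!r}")


@dataclass
class GroundTruth:
    hull_area_um2: float
    true_ratio: float
    pa_direction: np.ndarray             # unit (row, col) vector, posterior → anterior
    oocyte_fraction: float
    follicle_mask: np.ndarray
    nurse_mask: np.ndarray
    sector_counts: np.ndarray            # follicle px per 12 sectors (anterior origin, CCW)
    stage: int
    centroid: np.ndarray
    oocyte_offset: float | None          # boundary position along pa from centroid (px)


def spec_for_stage(stage: int, seed: int, rng: np.random.Generator | None = None,
                   pixel_size: float | None = None, **overrides) -> ChamberSpec:
    """Draw a stage-typical :class:`ChamberSpec` from the default models.

    When ``pixel_size`` is None a per-chamber magnification is chosen so
    the rendered semi-major axis stays near 90 px — emulating how an
    imager zooms to the object; absolute μm² features are calibration
    independent anyway.
    """
    if not (2 <= stage <= 12):
        raise ValueError("stages 2..12 are modeled")
    rng = rng or np.random.default_rng(seed)
    log_area = GROWTH_INTERCEPT + GROWTH_SLOPE * (stage - 2) + rng.normal(0, GROWTH_NOISE)
    area_um2 = float(np.exp(log_area))
    ratio = max(1.0, _ratio_for_stage(stage) + rng.normal(0, 0.1))
    if pixel_size is None:
        a_um = np.sqrt(area_um2 * ratio / np.pi)
        pixel_size = float(np.clip(a_um / 90.0, 0.5, 1.7))
    area_px = area_um2 / pixel_size**2
    b = float(np.sqrt(area_px / (np.pi * ratio)))
    a = float(ratio * b)
    ofrac = _oocyte_fraction_for_stage(stage)
    if ofrac > 0:
        ofrac = float(np.clip(ofrac + rng.normal(0, OOCYTE_NOISE), 0.05, 0.9))
    # rim nucleus spacing roughly constant in μm -> count scales with perimeter
    perim = np.pi * (3 * (a + b) - np.sqrt((3 * a + b) * (a + 3 * b)))
    r_f = max(1.8, 3.5 / pixel_size)   # follicle nucleus radius ~3.5 μm
    n_follicle = max(8, int(perim / (2.2 * r_f)))
    spec = ChamberSpec(
        stage=stage,
        axes=(a, b),
        ratio=ratio,
        n_follicle=n_follicle,
        follicle_uniformity=0.85 if stage >= 9 else 0.0,
        oocyte_fraction=ofrac,
        nurse_texture="blobby" if stage == 4 else "smooth",
        centripetal=(stage >= 11),
        pixel_size=pixel_size,
        seed=int(seed),
    )
    return replace(spec, **overrides) if overrides else spec


def _add_gaussian(img: np.ndarray, center: np.ndarray, sigma: float,
                  amplitude: float, hardness: float = 2.0) -> None:
    """Accumulate a (super-)Gaussian spot; ``hardness`` > 2 flattens the top."""
    r0, c0 = center
    rad = int(np.ceil(3.2 * sigma))
    nr, nc = img.shape
    rlo, rhi = max(0, int(r0) - rad), min(nr, int(r0) + rad + 1)
    clo, chi = max(0, int(c0) - rad), min(nc, int(c0) + rad + 1)
    if rlo >= rhi or clo >= chi:
        return
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    d2 = ((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2)
    patch = amplitude * np.exp(-(d2 ** (hardness / 2.0)))
    np.maximum(img[rlo:rhi, clo:chi], patch, out=img[rlo:rhi, clo:chi])


def _disk_mask(shape, center, radius) -> np.ndarray:
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _posterior_cut(a: float, frac: float) -> float:
    """Signed position p (along anterior direction) of the chord splitting
    off a posterior area fraction ``frac`` of the ellipse."""
    if frac <= 0:
        return -a  # no oocyte: the whole interior is nurse territory

    def posterior_fraction(t):
        # area fraction of the unit disk with coordinate <= t, by symmetry
        return (np.arccos(-t) - (-t) * np.sqrt(1 - t * t)) / np.pi

    t = brentq(lambda t: posterior_fraction(t) - frac, -1 + 1e-9, 1 - 1e-9)
    return float(t) * a   # oocyte occupies p < t*a (anterior coordinate)


def render_chamber(spec: ChamberSpec) -> tuple[ChamberImage, GroundTruth]:
    """Render one chamber and its ground truth.

    The anterior direction ``u`` is drawn uniformly; pixel coordinates are
    decomposed as p = (x-c)·u (anterior positive) and q = (x-c)·v.
    Ground-truth masks are recorded before noise is applied.
    """
    rng = np.random.default_rng(spec.seed)
    a, b = spec.axes
    r_f = max(1.8, 3.5 / spec.pixel_size)          # follicle nucleus radius, px
    pad = int(max(12, 0.15 * a)) + int(np.ceil(3 * r_f))
    side = int(np.ceil(2 * a)) + 2 * pad
    if side < 16:
        raise DegenerateInputError("chamber too small to render")
    shape = (side, side)
    center = np.array([side / 2.0, side / 2.0])
    theta = rng.uniform(0, 2 * np.pi)
    u = np.array([np.sin(theta), np.cos(theta)])   # anterior direction
    v = np.array([-u[1], u[0]])

    img = np.zeros(shape)
    follicle_mask = np.zeros(shape, dtype=bool)
    nurse_mask = np.zeros(shape, dtype=bool)

    # --- follicle ring ------------------------------------------------------
    # epithelium nuclei are near-evenly spaced along the rim: place them at
    # equal quantiles of the arc-length weight, so anterior thinning shows
    # up as wider spacing (stretched cells) rather than random gaps
    psi_grid = np.linspace(0, 2 * np.pi, 1441)
    arc_speed = np.hypot(a * np.sin(psi_grid), b * np.cos(psi_grid))
    thin_of = lambda psi: 1.0 - spec.follicle_uniformity * np.exp(
        -0.5 * (np.arctan2(np.sin(psi), np.cos(psi)) / 1.0) ** 2)
    # spacing widens only moderately (gaps must stay small); most of the
    # density contrast comes from the flattened, smaller stretched nuclei
    thin = np.clip(thin_of(psi_grid), 0.65, None)
    w = arc_speed * thin
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1]))])
    cum /= cum[-1]
    phase = rng.uniform(0, 1)
    targets = ((np.arange(spec.n_follicle) + 0.5) / spec.n_follicle
               + rng.normal(0, 0.1 / max(spec.n_follicle, 1), size=spec.n_follicle)
               + phase) % 1.0
    psis = np.interp(np.sort(targets), cum, psi_grid)
    f_centers = []
    for psi in psis:
        # stretched (anterior-thinned) nuclei flatten: smaller and dimmer,
        # but still comfortably above the detection threshold
        t_loc = float(np.clip(thin_of(psi), 0.4, 1.0))
        r_loc = r_f * (0.78 + 0.22 * t_loc)
        amp = 0.55 + 0.45 * t_loc
        cpt = center + (a - r_f) * np.cos(psi) * u + (b - r_f) * np.sin(psi) * v
        f_centers.append(cpt)
        _add_gaussian(img, cpt, sigma=r_loc / 1.6, amplitude=amp, hardness=2.4)
        follicle_mask |= _disk_mask(shape, cpt, r_loc)

    # --- oocyte boundary and nurse nuclei ----------------------------------
    p_cut = _posterior_cut(a, spec.oocyte_fraction)
    oocyte_offset = None if spec.oocyte_fraction <= 0 else p_cut
    # nurse nuclei occupy the interior anterior of the oocyte boundary
    lo_p = (-a if spec.oocyte_fraction <= 0 else oocyte_offset)
    anterior_len = a - lo_p
    r_n = min(0.30 * b, 0.22 * anterior_len)
    r_n = max(r_n, 2.2 * r_f / 2, 2.0)
    n_centers: list[np.ndarray] = []
    # nurse nuclei abut the epithelium closely enough for the average
    # filter to bridge the gap, yet keep an intensity valley so the active
    # contour still separates germline from follicle nuclei: centers stay
    # inside an ellipse eroded by the clearance margin (capped so small
    # dense chambers still fill their posterior tip)
    c_m = min(1.05 * r_n + 1.4 * r_f + 2.0, 0.5 * b)
    if a - c_m > 1 and b - c_m > 1:
        # nurse disks stay tangent to the oocyte boundary, not inside it
        p_lo = max(lo_p + 0.95 * r_n, -(a - c_m))

        def try_place(p):
            qmax = (b - c_m) * np.sqrt(max(0.0, 1 - (p / (a - c_m)) ** 2))
            if qmax <= 0:
                return False
            cpt = center + p * u + rng.uniform(-qmax, qmax) * v
            if any(np.hypot(*(cpt - other)) < 1.7 * r_n for other in n_centers):
                return False
            n_centers.append(cpt)
            return True

        # the oocyte boundary is defined by the abutting nurse cells:
        # guarantee one nucleus right at the boundary
        if spec.oocyte_fraction > 0 and spec.n_nurse > 0:
            for _ in range(60):
                if try_place(min(p_lo + 0.15 * r_n * rng.random(), a - c_m)):
                    break
        attempts = 0
        while len(n_centers) < spec.n_nurse and attempts < 4000:
            attempts += 1
            try_place(rng.uniform(p_lo, a - c_m))
    for cpt in n_centers:
        if spec.nurse_texture == "blobby":
            k = rng.integers(4, 7)
            for _ in range(k):
                off = rng.normal(0, 0.45 * r_n, size=2)
                off *= min(1.0, 0.62 * r_n / max(np.hypot(*off), 1e-9))
                _add_gaussian(img, cpt + off, sigma=r_n / 3.4, amplitude=0.9)
        else:
            _add_gaussian(img, cpt, sigma=r_n / 1.8, amplitude=0.85, hardness=3.0)
        nurse_mask |= _disk_mask(shape, cpt, r_n)

    # --- centripetal cells (stage 10B signature) ----------------------------
    centr_centers = []
    if spec.centripetal and oocyte_offset is not None:
        half_q = b * np.sqrt(max(0.0, 1 - (oocyte_offset / a) ** 2))
        for sign in (+1, -1):
            cpt = center + oocyte_offset * u + sign * (half_q - 2.2 * r_f) * v
            centr_centers.append(cpt)
            _add_gaussian(img, cpt, sigma=r_f / 1.6, amplitude=1.0, hardness=2.4)
            follicle_mask |= _disk_mask(shape, cpt, r_f)

    # --- ground truth (noise-free) ------------------------------------------
    nuc_pts = np.argwhere(follicle_mask | nurse_mask)
    if len(nuc_pts) < 3:
        raise DegenerateInputError("spec renders too few nuclei pixels")
    hull_px = rasterize_convex_points(nuc_pts.astype(float), shape)
    sector_counts = _sector_counts(follicle_mask, center, u, v)
    truth = GroundTruth(
        hull_area_um2=float(hull_px.sum()) * spec.pixel_size**2,
        true_ratio=float(a / b),
        pa_direction=u.copy(),
        oocyte_fraction=float(spec.oocyte_fraction),
        follicle_mask=follicle_mask,
        nurse_mask=nurse_mask,
        sector_counts=sector_counts,
        stage=spec.stage,
        centroid=center.copy(),
        oocyte_offset=oocyte_offset,
    )

    # --- noise ---------------------------------------------------------------
    noise = spec.noise
    standoff = 22.0 / spec.pixel_size + 3 * r_f  # keep distractors clear of the blur reach
    for _ in range(noise.n_distractors):
        for _try in range(50):
            cpt = np.array([rng.uniform(0, side), rng.uniform(0, side)])
            relc = cpt - center
            if (relc @ u / (a + standoff)) ** 2 + (relc @ v / (b + standoff)) ** 2 > 1:
                _add_gaussian(img, cpt, sigma=rng.uniform(1.0, 2.0) * r_f,
                              amplitude=noise.distractor_amplitude)
                break
    if noise.background_sd > 0:
        img = img + rng.normal(0, noise.background_sd, size=shape)
    img = np.clip(img, 0.0, 1.0)
    return ChamberImage(img, spec.pixel_size), truth


def _sector_counts(follicle_mask: np.ndarray, center, u, v, n_sectors: int = 12) -> np.ndarray:
    pts = np.argwhere(follicle_mask).astype(float)
    if len(pts) == 0:
        return np.zeros(n_sectors)
    rel = pts - center
    theta = np.arctan2(rel @ v, rel @ u) % (2 * np.pi)
    sec = np.minimum((theta // (2 * np.pi / n_sectors)).astype(int), n_sectors - 1)
    return np.bincount(sec, minlength=n_sectors).astype(float)


def generate_feature_table(n_per_stage: int, seed: int,
                           slope: float = GROWTH_SLOPE,
                           intercept: float = GROWTH_INTERCEPT,
                           noise: float = GROWTH_NOISE,
                           stages=range(2, 13)) -> tuple[pd.DataFrame, dict]:
    """Per-stage feature vectors drawn from the generative feature model.

    Returns the table (columns stage, area_um2, log_size, oocyte_fraction,
    chamber_ratio, delta_to_uniform) and the generating parameters, so
    recovery tests can compare fitted against true values.
    """
    if n_per_stage < 1:
        raise ValueError("n_per_stage must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for s in stages:
        for _ in range(n_per_stage):
            log_size = intercept + slope * (s - 2) + rng.normal(0, noise)
            ratio = max(1.0, _ratio_for_stage(s) + rng.normal(0, RATIO_NOISE if noise > 0 else 0))
            of = _oocyte_fraction_for_stage(s)
            if of > 0:
                of = float(np.clip(of + rng.normal(0, OOCYTE_NOISE if noise > 0 else 0), 0.0, 0.95))
            else:
                of = np.nan  # undefined before stage 6
            mu, sd = DELTA_EARLY if s <= 8 else DELTA_LATE
            delta = max(0.0, mu + rng.normal(0, sd if noise > 0 else 0))
            rows.append(dict(stage=s, area_um2=float(np.exp(log_size)),
                             log_size=float(log_size), oocyte_fraction=of,
                             chamber_ratio=float(ratio), delta_to_uniform=float(delta)))
    params = dict(slope=slope, intercept=intercept, noise=noise,
                  ratio_slope=RATIO_SLOPE, delta_early=DELTA_EARLY, delta_late=DELTA_LATE)
    return pd.DataFrame(rows), params
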