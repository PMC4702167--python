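"""Shared fixtures: oracle helpers and pre-rendered chambers."""
from __future__ import annotations

import numpy as np
import pytest

from eggstage.image import BinaryMask, ChamberImage
from eggstage.pipeline import extract_features
from eggstage.synthetic_data import render_chamber, spec_for_stage


def brute_force_otsu(pixels: np.ndarray, nbins: int = 256) -> float:
    """Independent Otsu oracle: exhaustive between-class-variance
    maximization over histogram cut points."""
    hist, edges = np.histogram(pixels.ravel(), bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    best_t, best_v = centers[0], -1.0
    total = hist.sum()
    for k in range(1, nbins):
        w0 = hist[:k].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = (hist[:k] * centers[:k]).sum() / w0
        m1 = (hist[k:] * centers[k:]).sum() / w1
        v = w0 * w1 * (m0 - m1) ** 2
        if v > best_v:
            best_v, best_t = v, 0.5 * (centers[k - 1] + centers[k])
    return best_t


def flood_fill_components(mask: np.ndarray) -> list[set]:
    """Independent connected-component oracle: BFS flood fill with
    8-connectivity, components returned in raster-scan discovery order."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    comps = []
    nr, nc = mask.shape
    for r0 in range(nr):
        for c0 in range(nc):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            comp = set()
            stack = [(r0, c0)]
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                comp.add((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < nr and 0 <= cc < nc and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
            comps.append(comp)
    return comps


def disk_mask(shape, center, radius):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def ellipse_mask(shape, center, a, b, theta=0.0):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    u = np.array([np.sin(theta), np.cos(theta)])
    p = (rr - center[0]) * u[0] + (cc - center[1]) * u[1]
    q = -(rr - center[0]) * u[1] + (cc - center[1]) * u[0]
    return (p / a) ** 2 + (q / b) ** 2 <= 1.0


@pytest.fixture(scope="session")
def stage8_chamber():
    """One mid-oogenesis rendered chamber with ground truth."""
    spec = spec_for_stage(8, seed=808)
    return render_chamber(spec)


@pytest.fixture(scope="session")
def stage8_extracted(stage8_chamber):
    img, truth = stage8_chamber
    return extract_features(img), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
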