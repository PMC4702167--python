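"""Readers and writers.

Images: single-channel TIFF (via tifffile) and PNG (via imageio).  A
multi-channel raster is rejected unless a channel index is given — the
pipeline is defined on the DAPI channel alone.

Config: flat TOML key-value file mapping onto the pipeline configuration.

Outputs: masks as 0/255 PNG, geometry and area as JSON, and an audit
montage of the segmentation intermediates as PNG.
"""
from __future__ import annotations

import json
import tomllib
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import DegenerateInputError
from .image import BinaryMask, ChamberImage
from .pipeline import PipelineConfig
from .segmentation import ChanVeseParams, SegmentationConfig


def read_image(path, pixel_size: float, channel: int | None = None) -> ChamberImage:
    """Load a cropped single-chamber grayscale image (TIFF or PNG)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if channel is None:
            raise DegenerateInputError(
                f"{path.name} has {arr.shape[-1] if arr.shape[-1] < 5 else arr.shape[0]}"
                " channels; set a channel index for multi-channel input"
            )
        arr = arr[..., channel] if arr.shape[-1] <= 4 else arr[channel]
    elif arr.ndim != 2:
        raise DegenerateInputError(f"unsupported image dimensionality {arr.ndim}")
    return ChamberImage(arr, pixel_size)


def write_image(path, image: ChamberImage) -> None:
    """Write intensities as TIFF (float32) or PNG (8-bit)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.normalized().pixels.astype(np.float32))
    else:
        iio.imwrite(path, (image.normalized().pixels * 255).astype(np.uint8))


def write_mask(path, mask: BinaryMask) -> None:
    iio.imwrite(Path(path), (mask.pixels.astype(np.uint8) * 255))


def write_geometry_json(path, geometry, hull_area: float) -> None:
    doc = {
        "hull_area_um2": hull_area,
        "centroid_rc": list(map(float, geometry.centroid)),
        "major_axis_rc": list(map(float, geometry.major_axis)),
        "sd_major_px": geometry.sd_major,
        "sd_minor_px": geometry.sd_minor,
        "ratio": geometry.ratio,
        "pa_direction_rc": (list(map(float, geometry.pa_direction))
                            if geometry.oriented else None),
        "flags": geometry.flags,
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def write_audit_montage(path, intermediates: dict) -> None:
    """PNG montage of the segmentation steps for visual quality control."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    keys = [k for k in ("normalized", "binary_initial", "filtered", "binary_filtered",
                        "largest_component", "denoised", "nuclei") if k in intermediates]
    fig, axes = plt.subplots(1, len(keys), figsize=(3 * len(keys), 3))
    for ax, key in zip(np.atleast_1d(axes), keys):
        obj = intermediates[key]
        ax.imshow(getattr(obj, "pixels", obj), cmap="gray")
        ax.set_title(key, fontsize=8)
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def load_config(path) -> PipelineConfig:
    """Read a flat TOML config; unknown keys raise."""
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    seg = SegmentationConfig()
    cv = seg.chan_vese
    pipe = PipelineConfig(segmentation=seg)
    handlers = {
        "otsu_scale": lambda v: setattr(seg, "otsu_scale", float(v)),
        "filter_window": lambda v: setattr(seg, "filter_window", int(v)),
        "chan_vese_mu": lambda v: setattr(cv, "mu", float(v)),
        "chan_vese_lambda1": lambda v: setattr(cv, "lambda1", float(v)),
        "chan_vese_lambda2": lambda v: setattr(cv, "lambda2", float(v)),
        "chan_vese_max_iter": lambda v: setattr(cv, "max_iter", int(v)),
        "chan_vese_circle_radius": lambda v: setattr(cv, "init_circle_radius", float(v)),
        "chan_vese_circle_spacing": lambda v: setattr(cv, "init_circle_spacing", float(v)),
        "orientation_shrink": lambda v: setattr(pipe, "orientation_shrink", float(v)),
        "follicle_shrink": lambda v: setattr(pipe, "follicle_shrink", float(v)),
        "oocyte_threshold": lambda v: setattr(pipe, "oocyte_threshold", float(v)),
        "n_axis_points": lambda v: setattr(pipe, "n_axis_points", int(v)),
        "n_sectors": lambda v: setattr(pipe, "n_sectors", int(v)),
        "pixel_size": lambda v: None,  # consumed by callers as a fallback
    }
    for key, value in doc.items():
        if key not in handlers:
            raise KeyError(f"unknown config key {key!r}")
        handlers[key](value)
    return pipe


def config_pixel_size_fallback(path) -> float | None:
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    return float(doc["pixel_size"]) if "pixel_size" in doc else None
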