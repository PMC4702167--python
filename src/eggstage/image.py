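"""Core raster containers.

A :class:`ChamberImage` is a single-channel grayscale cross section through
the middle plane of one egg chamber, together with the physical pixel size
(μm per pixel edge) recorded at acquisition time.  All downstream area
measurements are reported in μm² via this calibration.

A :class:`BinaryMask` is a boolean raster of the same shape tagged with the
name of the operation that produced it, so that audit trails through the
segmentation pipeline stay interpretable.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError


@dataclass(frozen=True)
class ChamberImage:
    """Grayscale raster plus physical calibration.

    Parameters
    ----------
    pixels
        2-D array of finite, non-negative intensities.  Integer rasters are
        kept as loaded; use :func:`normalize` for a unit-scale copy.
    pixel_size
        Physical edge length of one pixel in μm (> 0).
    """

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise DegenerateInputError(
                f"expected a 2-D raster with >=2 rows and columns, got shape {px.shape}"
            )
        if not np.all(np.isfinite(px)):
            raise DegenerateInputError("image contains non-finite intensities")
        if px.min() < 0:
            raise DegenerateInputError("image contains negative intensities")
        if not (self.pixel_size > 0):
            raise DegenerateInputError(f"pixel_size must be > 0, got {self.pixel_size}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def normalized(self) -> "ChamberImage":
        """Return a copy rescaled to [0, 1] by the dtype maximum.

        Float inputs are assumed to already live on a unit-like scale and
        are divided by their max only if it exceeds 1; integer inputs are
        divided by the dtype maximum so thresholds are dtype independent.
        """
        px = self.pixels
        if np.issubdtype(px.dtype, np.integer):
            out = px.astype(np.float64) / np.iinfo(px.dtype).max
        else:
            out = px.astype(np.float64)
            m = out.max()
            if m > 1.0:
                out = out / m
        return ChamberImage(out, self.pixel_size)


@dataclass
class BinaryMask:
    """Boolean raster with provenance tag."""

    pixels: np.ndarray
    provenance: str = ""
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise DegenerateInputError("mask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def count(self) -> int:
        return int(self.pixels.sum())
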