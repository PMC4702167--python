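"""End-to-end feature extraction: image in, feature vector out.

Composes segmentation → geometry → features and returns every
intermediate, so a failed or suspicious result can be audited visually.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError
from .features import (OocyteEstimate, SectorDistribution, interior_cells,
                       oocyte_boundary, sector_densities, separate_follicle_cells)
from .geometry import (ChamberGeometry, middle_axis, orient_pa_axis, pca_axes,
                       shrink_boundary)
from .image import ChamberImage
from .segmentation import (NucleiSegmentation, SegmentationConfig,
                           segment_chamber)
from .staging_stats import FeatureVector


@dataclass
class PipelineConfig:
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    orientation_shrink: float = 0.85   # radial factor for the orientation step
    follicle_shrink: float = 0.80      # tighter factor for follicle separation
    oocyte_threshold: float = 0.10
    n_axis_points: int = 30
    n_sectors: int = 12


@dataclass
class ChamberFeatures:
    features: FeatureVector
    segmentation: NucleiSegmentation
    geometry: ChamberGeometry
    oocyte: OocyteEstimate
    sectors: SectorDistribution | None
    intermediates: dict


def extract_features(image: ChamberImage, config: PipelineConfig | None = None) -> ChamberFeatures:
    """Measure one cropped DAPI chamber image.

    ``oocyte_fraction`` is None when no oocyte boundary is found (early
    stages); ``delta_to_uniform`` is None when no follicle cells survive
    the boundary separation.
    """
    config = config or PipelineConfig()
    result = segment_chamber(image, config.segmentation)
    seg = result.segmentation
    geom = pca_axes(seg)
    shrunk_orient = shrink_boundary(seg, config.orientation_shrink)
    geom = orient_pa_axis(seg.nuclei_mask, geom, shrunk_orient)
    axis = middle_axis(geom, seg, config.n_axis_points)

    shrunk_follicle = shrink_boundary(seg, config.follicle_shrink)
    follicle = separate_follicle_cells(seg.nuclei_mask, shrunk_follicle)
    nurse = interior_cells(seg.nuclei_mask, shrunk_follicle)
    # the oocyte scan runs on interior cells only: the follicle ring wraps
    # the posterior pole and would mask the DAPI-sparse oocyte otherwise
    oocyte = oocyte_boundary(nurse, axis, geom, seg, config.oocyte_threshold)
    sectors = None
    if follicle.pixels.any():
        try:
            sectors = sector_densities(follicle, geom, seg, config.n_sectors)
        except DegenerateInputError:
            sectors = None

    fv = FeatureVector(
        log_size=float(np.log(seg.hull_area)),
        chamber_ratio=float(geom.ratio),
        oocyte_fraction=float(oocyte.area_fraction) if oocyte.found else None,
        delta_to_uniform=float(sectors.delta_to_uniform) if sectors is not None else None,
    )
    inter = dict(result.intermediates)
    inter.update(shrunk_orientation=shrunk_orient, shrunk_follicle=shrunk_follicle,
                 middle_axis=axis, follicle_mask=follicle, nurse_mask=nurse)
    return ChamberFeatures(features=fv, segmentation=seg, geometry=geom,
                           oocyte=oocyte, sectors=sectors, intermediates=inter)
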