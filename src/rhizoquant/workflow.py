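"""End-to-end per-image root-hair measurement.

Chains the pipeline stages (float conversion, natural-breaks
reclassification, conditioned class query, vectorisation, attachment
cleaning, skeleton root length) into one call returning root length, Ha
and sHa for a single micrograph.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .image_pipeline import (
    ClassifiedRaster,
    HairComponentSet,
    RasterImage,
    ScaleCalibration,
    calibrate_scale,
    clean_components,
    extract_classes,
    reclassify,
    select_classes,
    to_float_band,
    vectorize,
)
from .morphometry import polyline_length, root_length, specific_hair_area

__all__ = ["RootHairAnalysis", "measure_root_hairs"]


@dataclass
class RootHairAnalysis:
    """Full result of one image run, including intermediates for audit."""

    root_length_mm: float
    Ha_mm2: float
    sHa_mm2_per_mm: float
    pixel_size: float
    classified: ClassifiedRaster
    hair_classes: list[int]
    root_classes: list[int]
    components: HairComponentSet  # cleaned; .removed holds the deletions


def measure_root_hairs(
    rgb_image: np.ndarray,
    pixel_size: float | None = None,
    scale: ScaleCalibration | None = None,
    k: int = 10,
    hair_class_ids: Sequence[int] | None = None,
    hair_intensity_window: tuple[float, float] = (0.35, 0.68),
    root_class_ids: Sequence[int] | None = None,
    root_intensity_window: tuple[float, float] = (0.0, 0.30),
    channel: str = "luminance",
    prune_mm: float = 0.3,
    root_polyline_mm: Sequence[tuple[float, float]] | None = None,
) -> RootHairAnalysis:
    """Measure root length, Ha and sHa on one RGB micrograph.

    Physical scale comes from ``pixel_size`` (mm/px) or a
    :class:`ScaleCalibration` built from the in-image scale segment (one of
    the two is required).  The hair and root classes of the k-class
    natural-breaks map are selected either explicitly by id (the operator's
    conditioned query) or by a class-mean intensity window.  When a manual
    root polyline (mm coordinates) is supplied it takes precedence over the
    skeleton-based root length.
    """
    if pixel_size is None:
        if scale is None:
            raise ValueError("provide pixel_size or a ScaleCalibration")
        pixel_size = calibrate_scale(scale)

    band = to_float_band(rgb_image, channel=channel, pixel_size=pixel_size)
    cr = reclassify(band, k=k)

    hair_ids = (list(hair_class_ids) if hair_class_ids is not None
                else select_classes(cr, band, *hair_intensity_window))
    root_ids = (list(root_class_ids) if root_class_ids is not None
                else select_classes(cr, band, *root_intensity_window))
    if not root_ids:
        raise ValueError("no classes matched the root query")

    # an image genuinely free of hairs matches no hair class: Ha is 0
    hair_mask = (extract_classes(cr, hair_ids) if hair_ids
                 else np.zeros_like(cr.labels, dtype=bool))
    root_mask = extract_classes(cr, root_ids)

    hcs = clean_components(vectorize(hair_mask, pixel_size), root_mask)
    Ha = hcs.Ha

    if root_polyline_mm is not None:
        length = polyline_length(root_polyline_mm)
    else:
        length = root_length(root_mask, pixel_size, prune_mm=prune_mm)
    sHa = specific_hair_area(Ha, length)

    return RootHairAnalysis(
        root_length_mm=length,
        Ha_mm2=Ha,
        sHa_mm2_per_mm=sHa,
        pixel_size=pixel_size,
        classified=cr,
        hair_classes=hair_ids,
        root_classes=root_ids,
        components=hcs,
    )
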