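"""Root-hair extraction pipeline for germinating-seed micrographs.

The workflow mirrors a GIS raster analysis: the RGB micrograph is converted
to a single floating-point band, reclassified into ``k`` intensity classes
by natural-breaks (Jenks) clustering, the classes corresponding to root
hairs are extracted with a conditioned query, the resulting binary raster is
vectorised into per-component polygons, and components not attached to the
root body are removed as false positives.  The retained area is the
projected root-hair area Ha (mm^2).

Physical units come from a scale segment of known length photographed in
every image (2 mm by default); polygons trace pixel edges exactly, so the
vector area of a component equals ``pixel_count * pixel_size**2`` with no
rasterisation loss.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from shapely.affinity import scale as shapely_scale
from shapely.geometry import box
from shapely.ops import unary_union

from .natural_breaks import BreaksResult, jenks_breaks, jenks_breaks_histogram

__all__ = [
    "RasterImage",
    "ScaleCalibration",
    "ClassifiedRaster",
    "HairComponent",
    "HairComponentSet",
    "to_float_band",
    "calibrate_scale",
    "reclassify",
    "extract_classes",
    "select_classes",
    "vectorize",
    "clean_components",
]

# 8-connectivity: hairs are thin and frequently diagonal.
_STRUCT8 = np.ones((3, 3), dtype=bool)

# BT.709 luminance weights for the RGB -> single band conversion.
_LUMA = np.array([0.2126, 0.7152, 0.0722])


@dataclass
class RasterImage:
    """Single-band floating-point intensity grid with physical pixel size."""

    pixels: np.ndarray  # 2-D float array
    pixel_size: float  # mm per pixel, isotropic

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("RasterImage expects a 2-D band")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("intensities must be finite")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class ScaleCalibration:
    """Endpoints (row, col) of the in-image scale segment and its length."""

    p1: tuple[float, float]
    p2: tuple[float, float]
    known_length: float = 2.0  # mm


def calibrate_scale(cal: ScaleCalibration) -> float:
    """mm-per-pixel from the scale segment: known length / pixel distance."""
    if cal.known_length <= 0:
        raise ValueError("known_length must be positive")
    d = float(np.hypot(cal.p1[0] - cal.p2[0], cal.p1[1] - cal.p2[1]))
    if d == 0:
        raise ValueError("scale endpoints coincide")
    return cal.known_length / d


def to_float_band(rgb_image: np.ndarray, channel: str = "luminance",
                  pixel_size: float = 1.0) -> RasterImage:
    """Convert a 3-channel raster to a single floating-point band in [0, 1].

    ``channel`` is ``"luminance"`` (BT.709 weights, the default) or one of
    ``"r" | "g" | "b"`` to use a single channel.  Integer input is rescaled
    by its dtype maximum; float input is assumed to already be in [0, 1].
    """
    arr = np.asarray(rgb_image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an RGB image with 3 channels")
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(rgb_image.dtype).max
    else:
        arr = arr.astype(np.float64)
    if channel == "luminance":
        band = arr @ _LUMA
    elif channel in ("r", "g", "b"):
        band = arr[:, :, "rgb".index(channel)]
    else:
        raise ValueError(f"unknown channel {channel!r}")
    return RasterImage(pixels=band, pixel_size=pixel_size)


@dataclass
class ClassifiedRaster:
    """Per-pixel class labels plus the natural-breaks result behind them."""

    labels: np.ndarray  # 2-D int array, values in 0..k-1
    breaks: BreaksResult

    @property
    def k(self) -> int:
        return self.breaks.k


def reclassify(img: RasterImage, k: int = 10, exact: bool = False,
               bins: int = 1024) -> ClassifiedRaster:
    """Reclassify a band into ``k`` natural-breaks intensity classes.

    For images with more than ``bins`` distinct intensities the breaks are
    computed on a ``bins``-bin histogram of the intensity range (exact
    whenever the data has <= ``bins`` distinct values, which covers 8-bit
    imagery); ``exact=True`` forces the per-value computation regardless.

    When the image has fewer distinct values than ``k``, every distinct
    value gets its own class (the effective k is reduced).
    """
    flat = img.pixels.ravel()
    distinct = np.unique(flat)
    k_eff = min(k, distinct.size)
    if exact or distinct.size <= bins:
        result = jenks_breaks(flat, k_eff)
    else:
        lo, hi = float(distinct[0]), float(distinct[-1])
        edges = np.linspace(lo, hi, bins + 1)
        counts, _ = np.histogram(flat, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        result = jenks_breaks_histogram(list(zip(centers, counts)), min(k_eff, int((counts > 0).sum())))
    labels = np.asarray(result.class_of(img.pixels), dtype=np.int32)
    return ClassifiedRaster(labels=labels, breaks=result)


def extract_classes(cr: ClassifiedRaster, class_ids: Iterable[int]) -> np.ndarray:
    """Binary mask of pixels whose class label is in ``class_ids``."""
    ids = sorted(set(int(i) for i in class_ids))
    if not ids:
        raise ValueError("conditioned query needs at least one class id")
    bad = [i for i in ids if not 0 <= i < cr.k]
    if bad:
        raise ValueError(f"class ids {bad} outside 0..{cr.k - 1}")
    return np.isin(cr.labels, ids)


def select_classes(cr: ClassifiedRaster, img: RasterImage,
                   lo: float, hi: float) -> list[int]:
    """Class ids whose mean pixel intensity lies in [lo, hi].

    This emulates the operator's conditioned query for the class(es) whose
    colour corresponds to root hairs: the operator knows the approximate
    intensity of the structure of interest and selects the classes covering
    it.  Class means (not break intervals) are used so a class that merely
    *abuts* the window from a different intensity mode is not dragged in.
    """
    if lo > hi:
        raise ValueError("lo must not exceed hi")
    means = ndimage.mean(img.pixels, labels=cr.labels, index=np.arange(cr.k))
    present = np.bincount(cr.labels.ravel(), minlength=cr.k) > 0
    return [int(i) for i in range(cr.k)
            if present[i] and lo <= means[i] <= hi]


@dataclass(frozen=True)
class HairComponent:
    """One connected component of the extracted hair raster."""

    label: int
    pixel_count: int
    area_mm2: float
    geometry: object  # shapely (Multi)Polygon in mm coordinates, pixel-edge exact
    touches_root: bool | None = None


@dataclass
class HairComponentSet:
    """Labelled hair components with their vector polygons and total area Ha."""

    components: list[HairComponent]
    labels: np.ndarray  # labelled component grid (0 = background)
    pixel_size: float
    removed: list[HairComponent] = field(default_factory=list)

    @property
    def Ha(self) -> float:
        """Total retained root-hair area projected on the image plane (mm^2)."""
        return float(sum(c.area_mm2 for c in self.components))

    def __len__(self) -> int:
        return len(self.components)


def _component_polygon(rows: np.ndarray, cols: np.ndarray, pixel_size: float):
    """Union of unit pixel squares, scaled to mm; area is pixel-edge exact."""
    geom = unary_union([box(c, r, c + 1, r + 1) for r, c in zip(rows, cols)])
    return shapely_scale(geom, xfact=pixel_size, yfact=pixel_size, origin=(0, 0))


def vectorize(mask: np.ndarray, pixel_size: float) -> HairComponentSet:
    """Raster -> vector conversion of a binary hair mask.

    Each 8-connected component becomes one polygon whose boundary traces
    pixel edges (no smoothing), so its area equals
    ``pixel_count * pixel_size**2`` exactly.  An empty mask yields an empty
    set with Ha = 0.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not pixel_size > 0:
        raise ValueError("pixel_size must be positive")
    lab, n = ndimage.label(mask, structure=_STRUCT8)
    comps: list[HairComponent] = []
    if n:
        objects = ndimage.find_objects(lab)
        for i, sl in enumerate(objects, start=1):
            sub = lab[sl] == i
            rows, cols = np.nonzero(sub)
            rows = rows + sl[0].start
            cols = cols + sl[1].start
            count = int(rows.size)
            comps.append(
                HairComponent(
                    label=i,
                    pixel_count=count,
                    area_mm2=count * pixel_size ** 2,
                    geometry=_component_polygon(rows, cols, pixel_size),
                )
            )
    return HairComponentSet(components=comps, labels=lab, pixel_size=pixel_size)


def clean_components(hcs: HairComponentSet, root_mask: np.ndarray) -> HairComponentSet:
    """Drop components not attached to the root body.

    A component is attached when at least one of its pixels is 8-adjacent
    to (or overlaps) ``root_mask``.  Returns a new set whose ``components``
    are the retained ones (flagged ``touches_root=True``) and whose
    ``removed`` list records the deletions for audit; Ha is recomputed over
    the retained components.  Cleaning is idempotent.
    """
    root_mask = np.asarray(root_mask, dtype=bool)
    if root_mask.shape != hcs.labels.shape:
        raise ValueError("root_mask shape must match the component grid")
    if not root_mask.any():
        warnings.warn("empty root mask: every component will be removed",
                      stacklevel=2)
        near = np.zeros_like(root_mask)
    else:
        near = ndimage.binary_dilation(root_mask, structure=_STRUCT8)
    touching = set(np.unique(hcs.labels[near & (hcs.labels > 0)]).tolist())
    kept, removed = [], list(hcs.removed)
    for c in hcs.components:
        attached = c.label in touching
        c2 = HairComponent(c.label, c.pixel_count, c.area_mm2, c.geometry,
                           touches_root=attached)
        (kept if attached else removed).append(c2)
    labels = np.where(np.isin(hcs.labels, [c.label for c in kept]),
                      hcs.labels, 0)
    return HairComponentSet(components=kept, labels=labels,
                            pixel_size=hcs.pixel_size, removed=removed)
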