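"""Synthetic root micrographs with exact ground truth.

No public micrograph dataset accompanies the root-hair method, so
end-to-end testing uses generated images that emulate the content of a
germinating-seed micrograph: a dark elongated root body following a curved
centerline of known arc length, thin lateral hair protrusions of
intermediate intensity rooted on the root boundary, a few detached specks
of hair-like intensity (planted false positives), a dark scale bar of known
physical length, and additive Gaussian noise on a light background.

Every fixture carries a :class:`GroundTruth` with the exact region masks,
the attached-hair area in mm^2 and the analytic centerline length, so the
pipeline's Ha and sHa can be checked against known answers.  A fixed seed
makes the image byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage.draw import disk, line

__all__ = ["SyntheticRootSpec", "GroundTruth", "generate",
           "default_fixture_grid", "write_fixture"]


@dataclass(frozen=True)
class SyntheticRootSpec:
    """Parameters of one synthetic micrograph.

    Defaults emulate the study conditions of the original assay: an 8x
    field of view holding a 10-12 mm root segment, a 2 mm scale bar, and a
    light background with dark root and intermediate-intensity hairs.
    """

    shape: tuple[int, int] = (480, 640)  # rows, cols (9.6 x 12.8 mm)
    pixel_size: float = 0.02  # mm per pixel
    margin_mm: float = 0.8  # gap between root ends and image border
    curvature_amplitude_mm: float = 0.6  # sine amplitude of the centerline
    curvature_cycles: float = 1.0
    root_width_mm: float = 0.5
    hair_count: int = 40
    hair_length_mm: tuple[float, float] = (0.3, 0.9)
    hair_width_px: int = 2
    speck_count: int = 5
    speck_radius_px: tuple[int, int] = (1, 3)
    background_intensity: float = 0.85
    root_intensity: float = 0.15
    hair_intensity: float = 0.50
    noise_sd: float = 0.03
    scale_bar_length_mm: float = 2.0
    seed: int = 0


@dataclass
class GroundTruth:
    """Exact per-fixture truth for validating the measurement pipeline."""

    root_mask: np.ndarray
    hair_mask: np.ndarray  # attached hairs only (disjoint from root_mask)
    speck_mask: np.ndarray  # planted detached false positives
    hair_attached: list[bool]
    attached_hair_area_mm2: float
    centerline_length_mm: float
    scale_p1: tuple[int, int]  # (row, col) endpoints of the scale bar
    scale_p2: tuple[int, int]
    pixel_size: float


def _centerline(spec: SyntheticRootSpec):
    """Dense centerline samples (row, col) and arc length in mm."""
    h, w = spec.shape
    m = spec.margin_mm / spec.pixel_size
    amp = spec.curvature_amplitude_mm / spec.pixel_size
    half_w = 0.5 * spec.root_width_mm / spec.pixel_size
    x0, x1 = m, w - 1 - m
    cy = 0.45 * h
    if x1 - x0 < 10:
        raise ValueError("margins leave no room for the root")
    if not (half_w + 2 <= cy - amp and cy + amp <= h - half_w - 2):
        raise ValueError("root geometry exceeds the canvas")
    x = np.linspace(x0, x1, int(4 * (x1 - x0)))
    phase = 2 * np.pi * spec.curvature_cycles * (x - x0) / (x1 - x0)
    y = cy + amp * np.sin(phase)
    seg = np.hypot(np.diff(x), np.diff(y))
    arc_mm = float(seg.sum() * spec.pixel_size)
    return np.column_stack([y, x]), arc_mm


def _rasterize_root(points: np.ndarray, half_width_px: float,
                    shape: tuple[int, int]) -> np.ndarray:
    cl = np.zeros(shape, bool)
    rr = np.clip(np.round(points[:, 0]).astype(int), 0, shape[0] - 1)
    cc = np.clip(np.round(points[:, 1]).astype(int), 0, shape[1] - 1)
    cl[rr, cc] = True
    dist = ndimage.distance_transform_edt(~cl)
    band = dist <= half_width_px
    # trim the round end caps so the body length matches the centerline arc
    cols = np.arange(shape[1])[None, :]
    band &= (cols >= points[:, 1].min()) & (cols <= points[:, 1].max())
    return band


def _draw_thick_line(mask: np.ndarray, p0: np.ndarray, p1: np.ndarray,
                     width_px: int) -> None:
    """Stamp a straight segment of the given pixel width onto ``mask``."""
    d = p1 - p0
    n = np.hypot(*d)
    if n == 0:
        return
    perp = np.array([-d[1], d[0]]) / n
    offsets = (np.arange(width_px) - (width_px - 1) / 2.0)
    h, w = mask.shape
    for o in offsets:
        a = np.round(p0 + perp * o).astype(int)
        b = np.round(p1 + perp * o).astype(int)
        rr, cc = line(a[0], a[1], b[0], b[1])
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        mask[rr[keep], cc[keep]] = True


def generate(spec: SyntheticRootSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one synthetic micrograph.

    Returns the RGB uint8 image and its :class:`GroundTruth`.  The output
    is a deterministic function of ``spec`` (including ``spec.seed``).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    half_w = 0.5 * spec.root_width_mm / spec.pixel_size

    points, arc_mm = _centerline(spec)
    root = _rasterize_root(points, half_w, spec.shape)

    # Hairs: rooted just inside the root boundary, pointing outward along
    # the local normal with a little angular jitter.
    hair = np.zeros(spec.shape, bool)
    attached: list[bool] = []
    n_pts = len(points)
    lo_i, hi_i = int(0.05 * n_pts), int(0.95 * n_pts)
    for _ in range(spec.hair_count):
        i = int(rng.integers(lo_i, hi_i))
        tangent = points[min(i + 4, n_pts - 1)] - points[max(i - 4, 0)]
        tangent = tangent / np.hypot(*tangent)
        normal = np.array([-tangent[1], tangent[0]])
        side = 1 if rng.random() < 0.5 else -1
        ang = np.deg2rad(rng.uniform(-20, 20))
        rot = np.array([[np.cos(ang), -np.sin(ang)],
                        [np.sin(ang), np.cos(ang)]])
        direction = rot @ (side * normal)
        length_px = rng.uniform(*spec.hair_length_mm) / spec.pixel_size
        base = points[i] + direction * (half_w - 1.0)
        tip = base + direction * length_px
        tip = np.clip(tip, [1, 1], [h - 2, w - 2])
        _draw_thick_line(hair, base, tip, spec.hair_width_px)
        attached.append(True)
    hair &= ~root

    # Scale bar: horizontal, top-left corner, drawn at root intensity.
    bar_len = int(round(spec.scale_bar_length_mm / spec.pixel_size))
    if bar_len + 20 >= w:
        raise ValueError("scale bar does not fit the canvas")
    bar = np.zeros(spec.shape, bool)
    bar_r, bar_c = 12, 10
    bar[bar_r - 1:bar_r + 2, bar_c:bar_c + bar_len + 1] = True
    if (bar & (root | hair)).any():
        raise ValueError("scale bar overlaps the root structure")

    # Detached specks: hair-like intensity, kept well clear (>= 2 px under
    # 8-connectivity) of every root structure so cleaning must remove them.
    occupied = ndimage.binary_dilation(root | hair | bar,
                                       structure=np.ones((3, 3), bool),
                                       iterations=4)
    speck = np.zeros(spec.shape, bool)
    placed = 0
    for _ in range(200 * max(spec.speck_count, 1)):
        if placed >= spec.speck_count:
            break
        r = int(rng.integers(*spec.speck_radius_px, endpoint=True))
        cr_ = int(rng.integers(r + 2, h - r - 2))
        cc_ = int(rng.integers(r + 2, w - r - 2))
        rr, cc = disk((cr_, cc_), r, shape=spec.shape)
        if occupied[rr, cc].any() or speck[rr, cc].any():
            continue
        speck[rr, cc] = True
        placed += 1
    if placed < spec.speck_count:
        raise ValueError("could not place all detached specks")

    img = np.full(spec.shape, spec.background_intensity)
    img[root | bar] = spec.root_intensity
    img[hair | speck] = spec.hair_intensity
    img += rng.normal(0.0, spec.noise_sd, size=spec.shape)
    np.clip(img, 0.0, 1.0, out=img)
    rgb = np.repeat(np.round(img * 255).astype(np.uint8)[:, :, None], 3, axis=2)

    gt = GroundTruth(
        root_mask=root,
        hair_mask=hair,
        speck_mask=speck,
        hair_attached=attached,
        attached_hair_area_mm2=float(hair.sum()) * spec.pixel_size ** 2,
        centerline_length_mm=arc_mm,
        scale_p1=(bar_r, bar_c),
        scale_p2=(bar_r, bar_c + bar_len),
        pixel_size=spec.pixel_size,
    )
    return rgb, gt


def default_fixture_grid(n: int = 20, base_seed: int = 0) -> list[SyntheticRootSpec]:
    """The default deterministic test grid of ``n`` fixture specs.

    Hair load, centerline curvature and speck count are cycled so the grid
    spans sparse to dense hair cover and straight to curved roots.
    """
    hair_counts = (10, 25, 40, 60)
    amplitudes = (0.2, 0.6, 1.0)
    specks = (3, 5, 8)
    return [
        SyntheticRootSpec(
            hair_count=hair_counts[i % len(hair_counts)],
            curvature_amplitude_mm=amplitudes[i % len(amplitudes)],
            speck_count=specks[i % len(specks)],
            seed=base_seed + i,
        )
        for i in range(n)
    ]


def write_fixture(directory: str | Path, name: str,
                  spec: SyntheticRootSpec) -> tuple[Path, Path]:
    """Materialise a fixture as PNG + JSON ground-truth sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rgb, gt = generate(spec)
    png = directory / f"{name}.png"
    meta = directory / f"{name}.json"
    iio.imwrite(png, rgb)
    sidecar = {
        "spec": asdict(spec),
        "pixel_size_mm": gt.pixel_size,
        "scale_p1": list(gt.scale_p1),
        "scale_p2": list(gt.scale_p2),
        "scale_length_mm": spec.scale_bar_length_mm,
        "attached_hair_area_mm2": gt.attached_hair_area_mm2,
        "centerline_length_mm": gt.centerline_length_mm,
        "speck_count": int(spec.speck_count),
    }
    meta.write_text(json.dumps(sidecar, indent=2))
    return png, meta
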