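"""Rosette segmentation and shape descriptors from top-view images.

Segmentation follows the classic color-threshold recipe for green tissue on
a dark background: invert the RGB image, move to HSV, and keep pixels whose
saturation falls inside a configurable band (default 35-255 on the 8-bit
scale).  Isolated specks are removed with a median-style outlier filter and
components below a minimum area are dropped.  Thresholds are configuration,
not constants: they depend on camera and light conditions and should be
re-tuned on template images for each setup.

Shape descriptors per labeled plant:

    RA    projected rosette area (pixel count, optionally cm^2)
    Perim crack-boundary perimeter (unit steps along pixel edges)
    Circ  4*pi*RA / Perim^2, clipped to <= 1
    AR    major / minor axis of the moment-equivalent ellipse
    Round 4*RA / (pi * major_axis^2)

The crack-boundary perimeter counts exposed pixel edges, so an axis-aligned
n x n square has perimeter exactly 4n; it is the bit-stable convention the
tests rely on.  Ellipse axes come from second central moments (the standard
particle-analysis convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage import measure
from skimage.color import rgb2hsv
from skimage.morphology import disk

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationConfig",
    "Calibration",
    "LabelMap",
    "RosetteRecord",
    "segment_plants",
    "label_and_assign",
    "calibrate",
    "measure_rosette",
    "crack_perimeter",
]

# 8-connectivity everywhere (components, merging); stated here once.
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class SegmentationConfig:
    """Thresholds and cleaning parameters for plant segmentation.

    saturation_low/high are on the 8-bit (0-255) saturation scale of the
    *inverted* image.  despeckle_radius_px is the radius of the median
    outlier-removal filter (0 disables it).  Components smaller than
    min_object_area_px are discarded.  grid_rows x grid_cols describes the
    pot grid used by :func:`label_and_assign`.
    """

    saturation_low: int = 35
    saturation_high: int = 255
    despeckle_radius_px: int = 1
    min_object_area_px: int = 10
    grid_rows: int = 1
    grid_cols: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.saturation_low <= self.saturation_high <= 255):
            raise ValueError(
                "require 0 <= saturation_low <= saturation_high <= 255"
            )
        if self.despeckle_radius_px < 0 or self.min_object_area_px < 0:
            raise ValueError("radii and areas must be >= 0")
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid must be at least 1 x 1")


@dataclass(frozen=True)
class Calibration:
    """Pixel-to-centimeter scale: px_per_cm pixels per centimeter."""

    px_per_cm: float

    def __post_init__(self) -> None:
        if not self.px_per_cm > 0:
            raise ValueError("px_per_cm must be > 0")

    def area_to_cm2(self, area_px: float) -> float:
        return area_px / self.px_per_cm**2

    def length_to_cm(self, length_px: float) -> float:
        return length_px / self.px_per_cm


@dataclass
class LabelMap:
    """Labeled plants (0 = background) and their pot-grid assignment."""

    labels: np.ndarray
    grid_assignment: dict[int, tuple[int, int]] = field(default_factory=dict)

    @property
    def n_plants(self) -> int:
        return int(self.labels.max())


@dataclass
class RosetteRecord:
    """Shape descriptors for one plant on one day."""

    plant_id: str
    day: float
    RA: float
    Perim: float
    Circ: float
    AR: float
    Round: float
    unit_flag: str = "pixels"  # "pixels" or "cm"


def _as_rgb(img: np.ndarray) -> np.ndarray:
    a = np.asarray(img)
    if a.ndim != 3 or a.shape[2] < 3:
        raise ValueError("expected an RGB image (H, W, 3)")
    return a[..., :3]


def segment_plants(img: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    """Segment plant tissue from a top-view RGB image.

    Pipeline: invert RGB, convert to HSV, keep pixels whose saturation
    (0-255 scale) lies in [saturation_low, saturation_high], despeckle with
    a median outlier filter, drop components below the minimum area.

    Returns a boolean mask.  An empty mask is legal (a warning is logged);
    downstream code decides what to do with it.
    """
    rgb = _as_rgb(img)
    if np.issubdtype(rgb.dtype, np.floating):
        rgb = np.clip(rgb, 0.0, 1.0)
        inverted = 1.0 - rgb
    else:
        inverted = 255 - rgb.astype(np.uint8)
    sat = rgb2hsv(inverted)[..., 1] * 255.0
    mask = (sat >= cfg.saturation_low) & (sat <= cfg.saturation_high)

    if cfg.despeckle_radius_px > 0 and mask.any():
        mask = _despeckle(mask, cfg.despeckle_radius_px)

    if cfg.min_object_area_px > 0 and mask.any():
        lab, n = ndi.label(mask, structure=_STRUCT8)
        if n:
            areas = np.bincount(lab.ravel())[1:]
            keep = np.flatnonzero(areas >= cfg.min_object_area_px) + 1
            mask = np.isin(lab, keep)

    if not mask.any():
        logger.warning("segmentation produced an empty mask")
    return mask


def _despeckle(mask: np.ndarray, radius: int, max_iter: int = 10) -> np.ndarray:
    """Median-style outlier removal: replace pixels deviating from the
    local median (disk footprint of the given radius) by that median,
    iterated to a fixed point so segmentation is idempotent."""
    footprint = disk(radius)
    out = mask.copy()
    for _ in range(max_iter):
        med = ndi.median_filter(out.astype(np.uint8), footprint=footprint)
        nxt = med.astype(bool)
        if np.array_equal(nxt, out):
            break
        out = nxt
    return out


def label_and_assign(mask: np.ndarray, cfg: SegmentationConfig) -> LabelMap:
    """Label 8-connected components and assign each to its pot-grid cell.

    Each component goes to the grid cell whose center is nearest its
    centroid (ties broken toward the lowest row, then column, and logged).
    Components sharing a cell are merged into a single plant.  Final labels
    are contiguous, ordered by cell in row-major order.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    lab, n = ndi.label(mask, structure=_STRUCT8)
    if n == 0:
        return LabelMap(labels=np.zeros_like(lab), grid_assignment={})

    cell_h = h / cfg.grid_rows
    cell_w = w / cfg.grid_cols
    centers = np.array(
        [
            [(i + 0.5) * cell_h, (j + 0.5) * cell_w]
            for i in range(cfg.grid_rows)
            for j in range(cfg.grid_cols)
        ]
    )
    centroids = ndi.center_of_mass(mask, lab, index=np.arange(1, n + 1))

    cell_members: dict[tuple[int, int], list[int]] = {}
    for comp, (cy, cx) in enumerate(centroids, start=1):
        d2 = (centers[:, 0] - cy) ** 2 + (centers[:, 1] - cx) ** 2
        best = float(d2.min())
        tied = np.flatnonzero(np.isclose(d2, best, rtol=0, atol=1e-9))
        if len(tied) > 1:
            logger.info(
                "component %d equidistant to %d cells; tie-break to lowest "
                "row, then column",
                comp,
                len(tied),
            )
        idx = int(tied[0])  # centers are row-major: lowest row, then col
        cell = (idx // cfg.grid_cols, idx % cfg.grid_cols)
        cell_members.setdefault(cell, []).append(comp)

    out = np.zeros_like(lab)
    assignment: dict[int, tuple[int, int]] = {}
    next_label = 1
    for cell in sorted(cell_members):
        comps = cell_members[cell]
        if len(comps) > 1:
            logger.info("merging %d components in cell %s", len(comps), cell)
        out[np.isin(lab, comps)] = next_label
        assignment[next_label] = cell
        next_label += 1
    return LabelMap(labels=out, grid_assignment=assignment)


def calibrate(calibrator_mask: np.ndarray, known_area_cm2: float) -> Calibration:
    """Derive the pixel scale from a surface calibrator of known area.

    px_per_cm = sqrt(pixel_area / known_area_cm2).
    """
    if known_area_cm2 <= 0:
        raise ValueError("known_area_cm2 must be > 0")
    area_px = int(np.count_nonzero(calibrator_mask))
    if area_px == 0:
        raise ValueError("calibrator mask is empty")
    return Calibration(px_per_cm=float(np.sqrt(area_px / known_area_cm2)))


def crack_perimeter(region_mask: np.ndarray) -> float:
    """Crack-boundary perimeter: number of pixel edges between foreground
    and background (image borders count).  Exact 4n for an n x n square."""
    m = np.pad(np.asarray(region_mask, dtype=bool), 1)
    edges = 0
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        edges += int(np.count_nonzero(m & ~np.roll(m, shift, axis=axis)))
    return float(edges)


def measure_rosette(
    labelmap: LabelMap,
    calib: Optional[Calibration] = None,
    day: float = 0.0,
    source_id: str = "",
) -> list[RosetteRecord]:
    """Measure the five shape descriptors for every labeled plant.

    Labels with fewer than 3 pixels are skipped with a warning (second
    moments are undefined).  With a calibration, RA and Perim are reported
    in cm^2 / cm; Circ, AR and Round are dimensionless either way.
    """
    labels = labelmap.labels
    records: list[RosetteRecord] = []
    for prop in measure.regionprops(labels):
        label = prop.label
        area_px = float(prop.area)
        if area_px < 3:
            logger.warning(
                "label %d has area %d px (< 3); skipped", label, int(area_px)
            )
            continue
        region = labels[prop.slice] == label
        perim_px = crack_perimeter(region)

        major = float(prop.axis_major_length)
        minor = float(prop.axis_minor_length)
        circ = 4.0 * np.pi * area_px / perim_px**2
        circ = min(circ, 1.0)  # digitized near-circles can overshoot
        ar = major / minor if minor > 0 else np.inf
        rnd = 4.0 * area_px / (np.pi * major**2) if major > 0 else 1.0
        rnd = min(rnd, 1.0)

        ra, perim, unit = area_px, perim_px, "pixels"
        if calib is not None:
            ra = calib.area_to_cm2(area_px)
            perim = calib.length_to_cm(perim_px)
            unit = "cm"
        cell = labelmap.grid_assignment.get(label)
        plant_id = (
            f"{source_id}r{cell[0]}c{cell[1]}" if cell else f"{source_id}p{label}"
        )
        records.append(
            RosetteRecord(
                plant_id=plant_id,
                day=day,
                RA=ra,
                Perim=perim,
                Circ=circ,
                AR=max(ar, 1.0),
                Round=rnd,
                unit_flag=unit,
            )
        )
    return records
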