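"""Colony and lumen segmentation and per-colony morphometrics.

The segmentation follows the classical high-content recipe: a global
intensity threshold separates live (dye-positive) colonies from
background, connected-components labeling identifies colonies, and size
filters remove debris, monolayers and out-of-focus objects. Lumens are
below-threshold cavities fully enclosed by a single colony's filled
footprint; cavities that open onto the background (for example a gap
between adjacent colonies) are rejected.

Circularity is 4*pi*Area / Perimeter^2 — 1 for a perfect circle, smaller
for irregular (spiky) outlines. The default perimeter estimator traces
the sub-pixel marching-squares contour of each region and simplifies it
with Douglas-Peucker (1 px tolerance), which removes the staircase bias
on oblique edges while leaving axis-aligned edges exact; a Crofton
4-direction estimator is available as an alternative.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure as skmeasure

logger = logging.getLogger(__name__)

PERIMETER_METHODS = ("contour", "crofton")


@dataclass(frozen=True)
class SegmentationParams:
    """Thresholds and filters for colony/lumen segmentation.

    ``intensity_threshold`` is an absolute count; alternatively set
    ``threshold_quantile`` to derive it from the image histogram. Size
    ranges are in px^2 and inclusive at both ends.
    """

    intensity_threshold: Optional[float] = 500.0
    threshold_quantile: Optional[float] = None
    colony_size_range: Tuple[float, float] = (200.0, 200_000.0)
    lumen_size_range: Tuple[float, float] = (20.0, 50_000.0)
    exclude_border: bool = True
    fill_holes_for_colony_mask: bool = True
    perimeter_method: str = "contour"

    def __post_init__(self) -> None:
        for lo, hi in (self.colony_size_range, self.lumen_size_range):
            if not lo < hi:
                raise ValueError("size range must satisfy min < max")
        if self.intensity_threshold is None and self.threshold_quantile is None:
            raise ValueError("one of intensity_threshold / threshold_quantile required")
        if self.threshold_quantile is not None and not 0.0 < self.threshold_quantile < 1.0:
            raise ValueError("threshold_quantile must be in (0, 1)")
        if self.perimeter_method not in PERIMETER_METHODS:
            raise ValueError(f"perimeter_method must be one of {PERIMETER_METHODS}")

    def threshold_for(self, image: np.ndarray) -> float:
        if self.threshold_quantile is not None:
            return float(np.quantile(image, self.threshold_quantile))
        return float(self.intensity_threshold)


@dataclass
class ColonyMeasurement:
    """Morphometrics of one segmented colony."""

    label: int
    area: float  # px^2 (pixel count)
    perimeter: float  # px
    circularity: float  # 4*pi*A/P^2, clamped to <= 1
    centroid: Tuple[float, float]  # (row, col)
    lumen_count: int = 0
    lumen_area_total: float = 0.0
    touches_border: bool = False


@dataclass
class WellSummary:
    """Per-well aggregates over retained colonies.

    ``pct_colonies_with_lumens`` is a percentage (0-100); summaries are
    NaN for an empty well.
    """

    colony_count: int
    median_colony_area: float
    pct_colonies_with_lumens: float
    median_circularity: float


def segment_colonies(image: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Label colonies in a single-channel image.

    Pixels at or above the threshold are foreground; 8-connected
    components are labeled, per-component holes filled (if configured),
    components outside the colony size range or touching the image border
    (if configured) removed, and survivors relabeled densely 1..K.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    if image.size == 0:
        raise ValueError("empty image")
    thr = params.threshold_for(image)
    fg = image >= thr
    if not fg.any():
        logger.warning("threshold %.3g above image maximum: empty labeling", thr)
        return np.zeros(image.shape, np.int32)

    labels, n = ndi.label(fg, structure=np.ones((3, 3), bool))
    if params.fill_holes_for_colony_mask and n:
        for lab, sl in enumerate(ndi.find_objects(labels), start=1):
            if sl is None:
                continue
            region = labels[sl] == lab
            filled = ndi.binary_fill_holes(region)
            # claim only pixels not already owned by another colony
            labels[sl][filled & (labels[sl] == 0)] = lab

    lo, hi = params.colony_size_range
    keep: List[int] = []
    for lab in range(1, n + 1):
        mask = labels == lab
        area = int(mask.sum())
        if not lo <= area <= hi:
            continue
        if params.exclude_border and _touches_border(mask):
            continue
        keep.append(lab)

    out = np.zeros(image.shape, np.int32)
    for new, lab in enumerate(keep, start=1):
        out[labels == lab] = new
    return out


def _touches_border(mask: np.ndarray) -> bool:
    return bool(mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any())


def detect_lumens(
    image: np.ndarray, colony_mask: np.ndarray, params: SegmentationParams
) -> Tuple[np.ndarray, Dict[int, int]]:
    """Find lumens: below-threshold cavities enclosed by single colonies.

    Returns a dense lumen label mask and a mapping lumen label -> colony
    label. A candidate cavity is rejected if any of its pixels is
    4-adjacent to pixels outside the colony's filled footprint (it opens
    onto the background, e.g. a gap between colonies) or if its area is
    outside ``lumen_size_range``.
    """
    image = np.asarray(image)
    colony_mask = np.asarray(colony_mask)
    if image.shape != colony_mask.shape:
        raise ValueError("image and colony mask shapes differ")
    thr = params.threshold_for(image)
    below = image < thr

    lumen_mask = np.zeros(image.shape, np.int32)
    assignment: Dict[int, int] = {}
    next_label = 1
    lo, hi = params.lumen_size_range
    cross = ndi.generate_binary_structure(2, 1)  # 4-connectivity for holes
    for lab, sl in enumerate(ndi.find_objects(colony_mask), start=1):
        if sl is None:
            continue
        # pad so footprint boundary adjacency is well-defined at the bbox edge
        region = np.pad(colony_mask[sl] == lab, 1)
        footprint = ndi.binary_fill_holes(region)
        cand = np.pad(below[sl], 1) & footprint
        comp, m = ndi.label(cand, structure=cross)
        if not m:
            continue
        outside = ~footprint
        for c in range(1, m + 1):
            cmask = comp == c
            area = int(cmask.sum())
            touches_out = bool((ndi.binary_dilation(cmask, cross) & outside).any())
            if touches_out or not lo <= area <= hi:
                continue
            target = lumen_mask[sl]
            target[cmask[1:-1, 1:-1]] = next_label
            assignment[next_label] = lab
            next_label += 1
    return lumen_mask, assignment


def circularity(area: float, perimeter: float) -> float:
    """Raw circularity 4*pi*Area/Perimeter^2 (no clamping)."""
    if area <= 0 or perimeter <= 0:
        raise ValueError("area and perimeter must be positive")
    return 4.0 * math.pi * area / perimeter**2


def region_perimeter(mask: np.ndarray, method: str = "contour") -> float:
    """Perimeter of a binary region.

    "contour": length of the Douglas-Peucker-simplified (1 px tolerance)
    marching-squares iso-contour — unbiased on straight edges, ~1% low on
    disks. "crofton": 4-direction Crofton line-intercept estimator.
    """
    mask = np.asarray(mask, bool)
    if method == "crofton":
        return float(skmeasure.perimeter_crofton(mask, directions=4))
    if method != "contour":
        raise ValueError(f"unknown perimeter method: {method}")
    padded = np.pad(mask.astype(float), 1)
    total = 0.0
    for contour in skmeasure.find_contours(padded, 0.5):
        poly = skmeasure.approximate_polygon(contour, tolerance=1.0)
        d = np.diff(poly, axis=0)
        total += float(np.hypot(d[:, 0], d[:, 1]).sum())
    return total


def measure_colonies(
    colony_mask: np.ndarray,
    lumen_mask: Optional[np.ndarray] = None,
    lumen_assignment: Optional[Dict[int, int]] = None,
    perimeter_method: str = "contour",
) -> List[ColonyMeasurement]:
    """Per-colony area, perimeter, circularity, centroid and lumen stats.

    Circularity is clamped to <= 1 here (rasterization can push the raw
    value slightly above 1 for near-circular regions).
    """
    colony_mask = np.asarray(colony_mask)
    if lumen_mask is not None and lumen_mask.shape != colony_mask.shape:
        raise ValueError("lumen mask shape differs from colony mask")
    lumen_counts: Dict[int, int] = {}
    lumen_areas: Dict[int, float] = {}
    if lumen_mask is not None and lumen_assignment:
        for lumen_label, colony_label in lumen_assignment.items():
            a = float((lumen_mask == lumen_label).sum())
            lumen_counts[colony_label] = lumen_counts.get(colony_label, 0) + 1
            lumen_areas[colony_label] = lumen_areas.get(colony_label, 0.0) + a

    out: List[ColonyMeasurement] = []
    for lab, sl in enumerate(ndi.find_objects(colony_mask), start=1):
        if sl is None:
            continue
        region = colony_mask[sl] == lab
        area = float(region.sum())
        perim = region_perimeter(region, method=perimeter_method)
        circ = min(circularity(area, perim), 1.0) if perim > 0 else float("nan")
        ys, xs = np.nonzero(region)
        centroid = (float(ys.mean() + sl[0].start), float(xs.mean() + sl[1].start))
        full = colony_mask == lab
        out.append(
            ColonyMeasurement(
                label=lab,
                area=area,
                perimeter=perim,
                circularity=circ,
                centroid=centroid,
                lumen_count=lumen_counts.get(lab, 0),
                lumen_area_total=lumen_areas.get(lab, 0.0),
                touches_border=_touches_border(full),
            )
        )
    return out


def summarize_well(measurements: Sequence[ColonyMeasurement]) -> WellSummary:
    """Aggregate a well: colony count, median area, % colonies with >=1
    lumen (0-100), median circularity. Empty wells yield NaN summaries."""
    n = len(measurements)
    if n == 0:
        return WellSummary(0, float("nan"), float("nan"), float("nan"))
    areas = np.array([m.area for m in measurements])
    circs = np.array([m.circularity for m in measurements])
    with_lumens = sum(1 for m in measurements if m.lumen_count >= 1)
    return WellSummary(
        colony_count=n,
        median_colony_area=float(np.median(areas)),
        pct_colonies_with_lumens=100.0 * with_lumens / n,
        median_circularity=float(np.nanmedian(circs)),
    )


def process_well_image(
    image: np.ndarray, params: SegmentationParams
) -> Tuple[np.ndarray, np.ndarray, Dict[int, int], List[ColonyMeasurement], WellSummary]:
    """Segment, detect lumens, measure and summarize one well image."""
    colony_mask = segment_colonies(image, params)
    lumen_mask, assignment = detect_lumens(image, colony_mask, params)
    measurements = measure_colonies(
        colony_mask, lumen_mask, assignment, perimeter_method=params.perimeter_method
    )
    return colony_mask, lumen_mask, assignment, measurements, summarize_well(measurements)


def measurements_to_frame(measurements: Sequence[ColonyMeasurement]) -> pd.DataFrame:
    """One row per colony, ready for CSV export."""
    return pd.DataFrame(
        {
            "label": [m.label for m in measurements],
            "area": [m.area for m in measurements],
            "perimeter": [m.perimeter for m in measurements],
            "circularity": [m.circularity for m in measurements],
            "centroid_row": [m.centroid[0] for m in measurements],
            "centroid_col": [m.centroid[1] for m in measurements],
            "lumen_count": [m.lumen_count for m in measurements],
            "lumen_area_total": [m.lumen_area_total for m in measurements],
            "touches_border": [m.touches_border for m in measurements],
        }
    )
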