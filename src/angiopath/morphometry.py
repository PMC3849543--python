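"""Per-vessel shape morphometry and image-level vascular density.

Measures per vessel: position, bounding box, area, perimeter, aspect ratio,
roundness (isoperimetric quotient, 4*pi*A/P^2) and perimeter ratio
(convex-hull perimeter over actual perimeter, a convexity/regularity
factor), each in pixels and in calibrated microns, for the outer contour
and, when present, the lumen.

Area and perimeter of traced digital boundaries (contours whose edges are
all unit chain steps) use bias-corrected digital estimators: the enclosed
pixel count via Pick's theorem (shoelace + N/2 + 1) and chain-length
weights 0.948 (straight) / 1.340 (diagonal), which are unbiased to well
under 1% for smooth shapes at vessel scale. Sparse vertex polygons are
measured exactly (shoelace area, Euclidean edges).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .imaging_core import Calibration, Contour, RasterImage, signed_area
from .hsv_stage import VesselContour

__all__ = [
    "MeasurementError",
    "ShapeMeasures",
    "MorphometryRecord",
    "DensityReport",
    "contour_area_px",
    "contour_perimeter_px",
    "measure_contour",
    "measure_vessel",
    "vascular_density",
]

# digitisation slack on the dimensionless shape factors
EPSILON = 0.05

_STRAIGHT_WEIGHT = 0.948
_DIAGONAL_WEIGHT = 1.340


class MeasurementError(ValueError):
    """Raised for degenerate contours that cannot be measured."""


def _edges(points: np.ndarray) -> np.ndarray:
    return np.diff(np.vstack([points, points[:1]]), axis=0)


def _is_chain(points: np.ndarray) -> bool:
    """True for traced digital boundaries: every edge is a unit chain step."""
    d = np.abs(_edges(points))
    return bool((d.max(axis=1) == 1).all())


def contour_area_px(points: np.ndarray) -> float:
    """Enclosed area in px^2 (Pick-corrected for digital boundaries)."""
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 2)
    a = abs(signed_area(pts))
    if _is_chain(pts):
        a += pts.shape[0] / 2.0 + 1.0
    return a


def contour_perimeter_px(points: np.ndarray) -> float:
    """Boundary length in px (chain-code weighted for digital boundaries)."""
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 2)
    d = _edges(pts)
    if _is_chain(pts):
        diag = np.abs(d).min(axis=1) == 1
        return float(_STRAIGHT_WEIGHT * np.sum(~diag)
                     + _DIAGONAL_WEIGHT * np.sum(diag))
    return float(np.linalg.norm(d, axis=1).sum())


def _hull_perimeter(points: np.ndarray) -> float:
    pts = np.asarray(points, dtype=np.float64)
    try:
        return float(ConvexHull(pts).area)  # in 2-D, .area is the perimeter
    except QhullError:
        # collinear points: hull degenerates to a segment
        span = pts.max(axis=0) - pts.min(axis=0)
        return 2.0 * float(np.hypot(*span))


@dataclass(frozen=True)
class ShapeMeasures:
    """Shape factors of one closed contour."""

    area_px: float
    area_um2: float
    width_px: int
    height_px: int
    width_um: float
    height_um: float
    perimeter_px: float
    perimeter_um: float
    aspect: float
    roundness: float
    perimeter_ratio: float


@dataclass
class MorphometryRecord:
    """One measurement row for one vessel (outer contour; lumen optional)."""

    vessel_id: int
    source: str
    position: Tuple[int, int]  # bbox top-left (x, y), px
    outer: ShapeMeasures
    inner: Optional[ShapeMeasures] = None

    def to_row(self) -> dict:
        """Flatten to one CSV/XLSX row; column names carry the units."""
        row = {
            "vessel_id": self.vessel_id,
            "source": self.source,
            "position_x_px": self.position[0],
            "position_y_px": self.position[1],
        }
        for prefix, m in (("", self.outer), ("lumen_", self.inner)):
            if m is None:
                for k in ("area_px2", "area_um2", "width_px", "height_px",
                          "width_um", "height_um", "perimeter_px",
                          "perimeter_um", "aspect", "roundness",
                          "perimeter_ratio"):
                    row[prefix + k] = ""
                continue
            row[prefix + "area_px2"] = m.area_px
            row[prefix + "area_um2"] = m.area_um2
            row[prefix + "width_px"] = m.width_px
            row[prefix + "height_px"] = m.height_px
            row[prefix + "width_um"] = m.width_um
            row[prefix + "height_um"] = m.height_um
            row[prefix + "perimeter_px"] = m.perimeter_px
            row[prefix + "perimeter_um"] = m.perimeter_um
            row[prefix + "aspect"] = m.aspect
            row[prefix + "roundness"] = m.roundness
            row[prefix + "perimeter_ratio"] = m.perimeter_ratio
        return row


@dataclass(frozen=True)
class DensityReport:
    """Image-level vascularisation summary.

    ``count_density`` is the classic microvessel density (vessels per mm^2
    of tissue); ``area_fraction`` is the fraction of the image area covered
    by vessel (outer-contour) area.
    """

    vessel_count: int
    image_area_um2: float
    count_density: float
    area_fraction: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.area_fraction <= 1.0):
            raise ValueError("area_fraction must be in [0, 1]")
        if self.count_density < 0:
            raise ValueError("count_density must be >= 0")


def measure_contour(contour: Contour, cal: Calibration) -> ShapeMeasures:
    """Measure one closed contour; raises :class:`MeasurementError` when
    degenerate (< 3 points)."""
    pts = contour.points
    if pts.shape[0] < 3:
        raise MeasurementError(
            f"contour with {pts.shape[0]} points cannot be measured")
    mpp = cal.microns_per_pixel
    area = contour_area_px(pts)
    per = contour_perimeter_px(pts)
    if area <= 0 or per <= 0:
        raise MeasurementError("degenerate contour (zero area or perimeter)")
    if _is_chain(pts):
        _, _, w, h = contour.bbox  # pixel extents (max - min + 1)
    else:  # sparse vertex polygon: geometric extents
        span = pts.max(axis=0) - pts.min(axis=0)
        w, h = int(span[0]), int(span[1])
    aspect = max(w, h) / min(w, h)
    roundness = 4.0 * math.pi * area / per ** 2
    perimeter_ratio = _hull_perimeter(pts) / per
    return ShapeMeasures(
        area_px=area,
        area_um2=area * mpp ** 2,
        width_px=w,
        height_px=h,
        width_um=w * mpp,
        height_um=h * mpp,
        perimeter_px=per,
        perimeter_um=per * mpp,
        aspect=aspect,
        roundness=roundness,
        perimeter_ratio=perimeter_ratio,
    )


def measure_vessel(v: VesselContour, cal: Optional[Calibration] = None,
                   vessel_id: int = 0) -> MorphometryRecord:
    """Measure a vessel's outer contour and, when present, its lumen."""
    cal = cal or Calibration()
    outer = measure_contour(v.outer, cal)
    inner = None
    if v.inner is not None and len(v.inner) >= 3:
        inner = measure_contour(v.inner, cal)
    x, y, _, _ = v.bbox
    return MorphometryRecord(
        vessel_id=vessel_id, source=v.source, position=(x, y),
        outer=outer, inner=inner,
    )


def vascular_density(records: Sequence[MorphometryRecord], image: RasterImage,
                     cal: Optional[Calibration] = None) -> DensityReport:
    """Vessel count per mm^2 and vessel area fraction for one image."""
    cal = cal or Calibration()
    image_area_um2 = image.width * image.height * cal.microns_per_pixel ** 2
    if image_area_um2 <= 0:
        raise ValueError("image area must be positive")
    n = len(records)
    total_vessel_um2 = float(sum(r.outer.area_um2 for r in records))
    return DensityReport(
        vessel_count=n,
        image_area_um2=image_area_um2,
        count_density=n / (image_area_um2 / 1e6),
        area_fraction=total_vessel_um2 / image_area_um2,
    )
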