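"""Stage (a): closed-vessel segmentation by HSV brown-colour thresholding.

DAB-stained endothelium appears brown on a pale background. Brown occupies
low hues at non-trivial saturation, so the stage thresholds the S and H
planes, combines them, cleans the mask morphologically, traces contours with
hole hierarchy and filters out small false positives (macrophage-sized
blobs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .imaging_core import (
    BinaryMask,
    Contour,
    RasterImage,
    extract_channel,
    find_contours,
    logical_not,
    logical_or,
    morph,
    rgb_to_hsv,
    signed_area,
    threshold,
)

__all__ = [
    "HsvStageConfig",
    "VesselContour",
    "segment_brown_mask",
    "cleanup",
    "extract_vessels",
    "pair_lumens",
    "filter_vessels",
]


@dataclass
class HsvStageConfig:
    """Parameters of the colour stage.

    ``s_threshold`` / ``h_threshold`` select saturated, low-hue (brown)
    pixels; ``erode_iters`` / ``dilate_iters`` remove small artifacts and
    join nearby structures; the size filter discards contours no larger than
    ``min_contour_points`` boundary points unless their bounding box exceeds
    ``min_bbox_px`` in both dimensions (see ``filter_combinator``).
    """

    s_threshold: int = 30
    h_threshold: int = 20
    erode_iters: int = 2
    dilate_iters: int = 4
    min_contour_points: int = 6
    min_bbox_px: int = 20
    edge_mode: str = "threshold"
    filter_combinator: str = "and"

    def __post_init__(self) -> None:
        if not 0 <= self.s_threshold <= 255:
            raise ValueError("s_threshold must be in [0, 255]")
        if not 0 <= self.h_threshold <= 179:
            raise ValueError("h_threshold must be in [0, 179]")
        for name in ("erode_iters", "dilate_iters", "min_contour_points",
                     "min_bbox_px"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.edge_mode not in ("threshold", "canny"):
            raise ValueError("edge_mode must be 'threshold' or 'canny'")
        if self.filter_combinator not in ("and", "or"):
            raise ValueError("filter_combinator must be 'and' or 'or'")


@dataclass
class VesselContour:
    """A segmented vessel: outer boundary, optional lumen, and provenance.

    ``source`` records which stage emitted it (``"hsv"`` closed-vessel colour
    stage, ``"radial"`` lumen-closing stage). ``inner``, when present, is the
    lumen boundary and lies inside ``outer``.
    """

    outer: Contour
    inner: Optional[Contour] = None
    source: str = "hsv"

    def __post_init__(self) -> None:
        if self.source not in ("hsv", "radial"):
            raise ValueError("source must be 'hsv' or 'radial'")

    @property
    def bbox(self) -> Tuple[int, int, int, int]:
        """Tight axis-aligned bounding box ``(x, y, w, h)`` of the outer
        contour."""
        return self.outer.bbox

    @property
    def centroid(self) -> Tuple[float, float]:
        """Mean of the outer boundary points, ``(x, y)``."""
        c = self.outer.points.mean(axis=0)
        return (float(c[0]), float(c[1]))


def segment_brown_mask(img: RasterImage, cfg: Optional[HsvStageConfig] = None
                       ) -> BinaryMask:
    """Segment brown-stained pixels of an RGB image.

    Inverted threshold on S (drops unsaturated background) OR normal
    threshold on H (drops high-hue colours, e.g. haematoxylin blue), then
    NOT: foreground = S > s_threshold and H <= h_threshold.
    """
    cfg = cfg or HsvStageConfig()
    hsv = rgb_to_hsv(img)
    h_plane = extract_channel(hsv, 0)
    s_plane = extract_channel(hsv, 1)
    s_low = threshold(s_plane, cfg.s_threshold, inverted=True)
    h_high = threshold(h_plane, cfg.h_threshold, inverted=False)
    return logical_not(logical_or(s_low, h_high))


def cleanup(mask: BinaryMask, cfg: Optional[HsvStageConfig] = None) -> BinaryMask:
    """Remove small artifacts and join nearby structures (erode then dilate)."""
    cfg = cfg or HsvStageConfig()
    out = morph(mask, "erode", cfg.erode_iters)
    return morph(out, "dilate", cfg.dilate_iters)


def pair_lumens(contours: Sequence[Contour]) -> List[VesselContour]:
    """Pair each outer contour with its largest-area hole as the lumen."""
    vessels: List[VesselContour] = []
    for idx, c in enumerate(contours):
        if c.is_hole:
            continue
        holes = [h for h in contours
                 if h.is_hole and h.parent_id == idx and len(h) >= 3]
        inner = max(holes, key=lambda h: abs(signed_area(h.points)), default=None)
        vessels.append(VesselContour(outer=c, inner=inner, source="hsv"))
    return vessels


def _keep(v: VesselContour, cfg: HsvStageConfig) -> bool:
    npts = len(v.outer)
    _, _, w, h = v.bbox
    big_enough = w > cfg.min_bbox_px and h > cfg.min_bbox_px
    if cfg.filter_combinator == "and":
        return npts > cfg.min_contour_points and big_enough
    return npts > cfg.min_contour_points or big_enough


def filter_vessels(vessels: Sequence[VesselContour], cfg: HsvStageConfig
                   ) -> List[VesselContour]:
    """Apply the small-artifact (macrophage) size filter."""
    return [v for v in vessels if _keep(v, cfg)]


def extract_vessels(source, cfg: Optional[HsvStageConfig] = None
                    ) -> List[VesselContour]:
    """Trace contours of a cleaned mask and keep the valid vessels.

    ``source`` is the cleaned :class:`BinaryMask` (``edge_mode="threshold"``)
    or, with ``edge_mode="canny"``, the pre-threshold grey
    :class:`RasterImage` whose Canny edges are traced instead.
    """
    cfg = cfg or HsvStageConfig()
    contours = find_contours(source, edge_mode=cfg.edge_mode)
    return filter_vessels(pair_lumens(contours), cfg)
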