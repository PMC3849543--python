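"""Stage (b): open-vessel detection by radial probing from the lumen.

Vascular lumens are bright (near-white) in brightfield IHC. The stage
extracts bright regions from the green channel, cleans them, and for each
candidate lumen probes outward along the boundary normals looking for brown
membrane pixels (stage (a)'s colour mask). A lumen is accepted when the
fraction of boundary points whose probe hits membrane reaches a
size-adjusted threshold; accepted lumens are closed into vessel contours.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .imaging_core import (
    BinaryMask,
    Contour,
    RasterImage,
    extract_channel,
    fill_small_holes,
    find_contours,
    morph,
    rasterise_contour,
    signed_area,
    threshold,
)
from .hsv_stage import HsvStageConfig, VesselContour, filter_vessels

__all__ = [
    "RadialStageConfig",
    "LumenCandidate",
    "extract_lumen_candidates",
    "boundary_normal",
    "membrane_hit_ratio",
    "evaluate_candidates",
    "validate_and_close",
]

# Half-window (in contour points) for tangent estimation by central
# difference; smaller windows are too noisy on digital curves.
NORMAL_HALF_WINDOW = 2


@dataclass
class RadialStageConfig:
    """Parameters of the lumen-closing stage.

    ``green_threshold`` separates bright lumens from tissue in the green
    plane. The erode/dilate/fill/erode sequence removes bright specks, fills
    small dark inclusions (< ``max_hole_px``) and pulls the lumen boundary
    off the membrane. Probes run outward along the boundary normal at
    integer offsets in [``probe_min_px``, ``probe_max_px``]. A lumen is
    valid when its membrane hit ratio reaches ``base_ratio``; short contours
    (< ``small_contour_points`` points) are more artifact-prone and must
    reach ``small_ratio`` instead.
    """

    green_threshold: int = 236
    erode_iters: int = 3
    dilate_iters: int = 2
    max_hole_px: int = 400
    second_erode_iters: int = 1
    probe_min_px: int = 2
    probe_max_px: int = 30
    base_ratio: float = 0.60
    small_contour_points: int = 100
    small_ratio: float = 0.80

    def __post_init__(self) -> None:
        if not 0 <= self.green_threshold <= 255:
            raise ValueError("green_threshold must be in [0, 255]")
        for name in ("erode_iters", "dilate_iters", "max_hole_px",
                     "second_erode_iters", "small_contour_points"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.base_ratio <= self.small_ratio <= 1.0:
            raise ValueError("need 0 <= base_ratio <= small_ratio <= 1")
        if not self.probe_min_px < self.probe_max_px:
            raise ValueError("probe_min_px must be < probe_max_px")

    @property
    def net_erosion_px(self) -> int:
        """Net boundary offset (px) accumulated by the cleanup sequence."""
        return self.erode_iters - self.dilate_iters + self.second_erode_iters


@dataclass
class LumenCandidate:
    """A potential vascular lumen with its membrane support."""

    contour: Contour
    hit_ratio: float
    valid: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.hit_ratio <= 1.0:
            raise ValueError("hit_ratio must be in [0, 1]")


def extract_lumen_candidates(img: RasterImage,
                             cfg: Optional[RadialStageConfig] = None
                             ) -> List[Contour]:
    """Bright-region pipeline: green channel -> threshold -> erode -> dilate
    -> fill small holes -> second erode -> outer contours."""
    cfg = cfg or RadialStageConfig()
    if img.colour_model != "RGB":
        raise ValueError("extract_lumen_candidates requires an RGB image")
    green = extract_channel(img, 1)
    mask = threshold(green, cfg.green_threshold, inverted=False)
    mask = morph(mask, "erode", cfg.erode_iters)
    mask = morph(mask, "dilate", cfg.dilate_iters)
    mask = fill_small_holes(mask, cfg.max_hole_px)
    mask = morph(mask, "erode", cfg.second_erode_iters)
    return [c for c in find_contours(mask) if not c.is_hole]


def _tangents(points: np.ndarray, k: int) -> np.ndarray:
    """Cyclic central-difference tangents for every contour point.

    Degenerate (zero) tangents fall back to progressively wider windows.
    """
    n = points.shape[0]
    t = np.roll(points, -k, axis=0) - np.roll(points, k, axis=0)
    bad = np.flatnonzero((t == 0).all(axis=1))
    for i in bad:
        for kk in range(k + 1, n // 2 + 1):
            d = points[(i + kk) % n] - points[(i - kk) % n]
            if d.any():
                t[i] = d
                break
        else:
            t[i] = (1, 0)  # fully degenerate contour; arbitrary direction
    return t.astype(np.float64)


def _outward_normals(contour: Contour, k: int = NORMAL_HALF_WINDOW) -> np.ndarray:
    """Unit outward normals at every contour point, (N, 2) float."""
    pts = contour.points
    t = _tangents(pts, k)
    # rotate the tangent 90 deg; the winding (shoelace sign) fixes which
    # rotation points away from the interior
    if signed_area(pts) >= 0:
        n = np.stack([t[:, 1], -t[:, 0]], axis=1)
    else:
        n = np.stack([-t[:, 1], t[:, 0]], axis=1)
    return n / np.linalg.norm(n, axis=1, keepdims=True)


def boundary_normal(contour: Contour, i: int, k: int = NORMAL_HALF_WINDOW
                    ) -> np.ndarray:
    """Unit outward normal at contour point ``i``.

    The tangent is the central difference between points ``i - k`` and
    ``i + k`` (cyclic); the normal is the tangent rotated 90 degrees towards
    the outside, as decided by the contour's winding orientation. Reversing
    the traversal order flips the tangent but not the outward normal.
    """
    n = len(contour)
    if n < 2 * k + 1:
        raise ValueError(f"contour has {n} points, need >= {2 * k + 1}")
    return _outward_normals(contour, k)[i % n]


def membrane_hit_ratio(contour: Contour, membrane: BinaryMask,
                       cfg: Optional[RadialStageConfig] = None) -> float:
    """Fraction of boundary points whose outward probe hits membrane.

    Each boundary point ``p`` samples ``p + t * n`` for integer offsets
    ``t`` in [probe_min_px, probe_max_px]; a point is a hit iff any sample
    lands on membrane foreground. Samples outside the image are misses.
    """
    cfg = cfg or RadialStageConfig()
    pts = contour.points.astype(np.float64)
    if pts.shape[0] == 0:
        return 0.0
    normals = _outward_normals(contour)
    offsets = np.arange(cfg.probe_min_px, cfg.probe_max_px + 1, dtype=np.float64)
    # samples: (N points, T offsets, 2)
    samples = pts[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    sx = np.rint(samples[..., 0]).astype(np.intp)
    sy = np.rint(samples[..., 1]).astype(np.intp)
    h, w = membrane.pixels.shape
    inside = (sx >= 0) & (sx < w) & (sy >= 0) & (sy < h)
    fg = membrane.as_bool()
    hit = np.zeros(sx.shape, dtype=bool)
    hit[inside] = fg[sy[inside], sx[inside]]
    return float(hit.any(axis=1).mean())


def evaluate_candidates(candidates: Sequence[Contour], membrane: BinaryMask,
                        cfg: Optional[RadialStageConfig] = None
                        ) -> List[LumenCandidate]:
    """Score every candidate lumen against the size-adjusted ratio threshold."""
    cfg = cfg or RadialStageConfig()
    out = []
    for c in candidates:
        ratio = membrane_hit_ratio(c, membrane, cfg)
        theta = (cfg.small_ratio if len(c) < cfg.small_contour_points
                 else cfg.base_ratio)
        out.append(LumenCandidate(contour=c, hit_ratio=ratio,
                                  valid=ratio >= theta))
    return out


def validate_and_close(candidates: Sequence[Contour], membrane: BinaryMask,
                       cfg: Optional[RadialStageConfig] = None,
                       filter_cfg: Optional[HsvStageConfig] = None
                       ) -> List[VesselContour]:
    """Accept supported lumens and close them into vessel contours.

    Each valid lumen is dilated back by the cleanup's net erosion (to restore
    the boundary position), re-traced, and emitted with the original lumen
    as the inner contour. The colour stage's small-artifact size filter
    (``filter_cfg``) is applied to the result.
    """
    cfg = cfg or RadialStageConfig()
    filter_cfg = filter_cfg or HsvStageConfig()
    shape = membrane.pixels.shape
    vessels: List[VesselContour] = []
    for cand in evaluate_candidates(candidates, membrane, cfg):
        if not cand.valid:
            continue
        region = rasterise_contour(cand.contour, shape, fill=True)
        if cfg.net_erosion_px > 0:
            region = morph(region, "dilate", cfg.net_erosion_px)
        traced = [c for c in find_contours(region) if not c.is_hole]
        if not traced:  # pragma: no cover - rasterised region is never empty
            continue
        outer = max(traced, key=lambda c: abs(signed_area(c.points)))
        vessels.append(VesselContour(outer=outer, inner=cand.contour,
                                     source="radial"))
    return filter_vessels(vessels, filter_cfg)
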