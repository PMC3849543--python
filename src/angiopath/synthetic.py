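"""Synthetic IHC-like scenes with per-object ground truth.

The generator emulates the appearance the segmenter is built for: a pale
tissue background, brown (DAB-like) annular vessels with bright near-white
lumens — closed, or open with an arc of the ring erased — and small solid
brown blobs standing in for macrophages (the false-positive class). Object
placement, colour jitter and pixel noise are all driven by one seed, so a
scene is bit-reproducible.

Ground truth is object-level (centre, radii, gap arc), which is what the
sensitivity/specificity scorer consumes: vessels are the positive class,
distractor blobs the negative class.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .imaging_core import RasterImage
from .hsv_stage import VesselContour

__all__ = [
    "SceneSpec",
    "GroundTruthObject",
    "generate_scene",
    "confusion_matrix",
    "score_detections",
    "sample_benchmark_spec",
    "truth_to_json",
    "truth_from_json",
]

# Palette (RGB). Vessel brown sits at H ~ 14, S ~ 187 under the 8-bit HSV
# convention, comfortably inside the colour stage's thresholds even with
# per-object jitter; the lumen's green value clears the bright-lumen
# threshold; the background is pale pink with hue far above the brown band.
VESSEL_RGB = (150, 90, 40)
LUMEN_RGB = (250, 250, 250)
BACKGROUND_RGB = (242, 228, 232)
COLOUR_JITTER = 8  # max +- per channel, per object

# minimum clearance between object outer boundaries, px; keeps objects
# separated through the colour stage's net dilation
MIN_SEPARATION = 14
# minimum lumen radius, px; the lumen must survive the radial stage's erosion
MIN_LUMEN_RADIUS = 6


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene.

    Defaults describe a mid-density TMA-core field: a 1024 x 1024 px image
    with 30 vessels (half closed, half open with gaps up to 30% of the
    circumference) and 20 macrophage-like distractors.
    """

    width: int = 1024
    height: int = 1024
    n_closed: int = 15
    n_open: int = 15
    n_distractors: int = 20
    radius_range: Tuple[int, int] = (15, 40)
    ring_thickness_range: Tuple[int, int] = (6, 12)
    gap_fraction_range: Tuple[float, float] = (0.10, 0.30)
    distractor_diameter_range: Tuple[int, int] = (6, 14)
    noise_sigma: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_closed", "n_open", "n_distractors"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.width < 1 or self.height < 1:
            raise ValueError("scene must be at least 1x1")
        lo, hi = self.gap_fraction_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("gap fractions must lie in (0, 0.5]")
        if self.distractor_diameter_range[1] > 15:
            raise ValueError("distractor diameter must be <= 15 px")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class GroundTruthObject:
    """One drawn object: a vessel (closed or open) or a distractor blob."""

    kind: str  # closed_vessel | open_vessel | distractor
    centre: Tuple[float, float]  # (x, y) px
    outer_radius: float
    lumen_radius: float = 0.0
    gap_arc: Optional[Tuple[float, float]] = None  # (start deg, extent deg)

    def __post_init__(self) -> None:
        if self.kind not in ("closed_vessel", "open_vessel", "distractor"):
            raise ValueError(f"unknown ground-truth kind {self.kind!r}")
        if self.kind != "distractor" and not (
                self.lumen_radius < self.outer_radius):
            raise ValueError("vessel lumen_radius must be < outer_radius")

    @property
    def is_vessel(self) -> bool:
        return self.kind != "distractor"


def _place(rng: np.random.Generator, spec: SceneSpec,
           radii: Sequence[float]) -> List[Tuple[float, float]]:
    """Rejection-sample non-overlapping centres for the given outer radii."""
    centres: List[Tuple[float, float]] = []
    placed_r: List[float] = []
    for r in radii:
        margin = r + 2
        for _ in range(500):
            cx = rng.uniform(margin, spec.width - margin)
            cy = rng.uniform(margin, spec.height - margin)
            if all((cx - px) ** 2 + (cy - py) ** 2
                   >= (r + pr + MIN_SEPARATION) ** 2
                   for (px, py), pr in zip(centres, placed_r)):
                centres.append((cx, cy))
                placed_r.append(r)
                break
        else:
            raise RuntimeError(
                "infeasible packing: could not place all objects; "
                "reduce object count or radii"
            )
    return centres


def _jittered_brown(rng: np.random.Generator) -> np.ndarray:
    base = np.array(VESSEL_RGB, dtype=np.int64)
    return np.clip(
        base + rng.integers(-COLOUR_JITTER, COLOUR_JITTER + 1, size=3),
        0, 255,
    )


def generate_scene(spec: SceneSpec) -> Tuple[RasterImage, List[GroundTruthObject]]:
    """Render a scene and return it with its ground truth.

    Deterministic for a fixed spec (including ``seed``): identical calls
    produce bit-identical images.
    """
    rng = np.random.default_rng(spec.seed)

    # sample object geometry first (placement needs the radii)
    kinds = (["closed_vessel"] * spec.n_closed
             + ["open_vessel"] * spec.n_open
             + ["distractor"] * spec.n_distractors)
    radii = []
    geoms = []
    for kind in kinds:
        if kind == "distractor":
            d = rng.integers(spec.distractor_diameter_range[0],
                             spec.distractor_diameter_range[1] + 1)
            geoms.append({"outer": d / 2.0})
            radii.append(d / 2.0)
        else:
            R = float(rng.integers(spec.radius_range[0],
                                   spec.radius_range[1] + 1))
            t = float(rng.integers(spec.ring_thickness_range[0],
                                   spec.ring_thickness_range[1] + 1))
            t = min(t, R - MIN_LUMEN_RADIUS)
            geom = {"outer": R, "lumen": R - t}
            if kind == "open_vessel":
                gap_frac = rng.uniform(*spec.gap_fraction_range)
                geom["gap"] = (float(rng.uniform(0.0, 360.0)),
                               float(gap_frac * 360.0))
            geoms.append(geom)
            radii.append(R)
    centres = _place(rng, spec, radii)

    img = np.empty((spec.height, spec.width, 3), dtype=np.float64)
    img[:] = BACKGROUND_RGB
    truth: List[GroundTruthObject] = []

    for kind, geom, (cx, cy) in zip(kinds, geoms, centres):
        R = geom["outer"]
        x0, x1 = int(math.floor(cx - R - 1)), int(math.ceil(cx + R + 2))
        y0, y1 = int(math.floor(cy - R - 1)), int(math.ceil(cy + R + 2))
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dist = np.hypot(xx - cx, yy - cy)
        patch = img[y0:y1, x0:x1]
        colour = _jittered_brown(rng)
        if kind == "distractor":
            patch[dist <= R] = colour
            truth.append(GroundTruthObject(kind, (cx, cy), R))
            continue
        r_lumen = geom["lumen"]
        ring = (dist <= R) & (dist > r_lumen)
        if kind == "open_vessel":
            start, extent = geom["gap"]
            ang = np.degrees(np.arctan2(yy - cy, xx - cx)) % 360.0
            in_gap = (ang - start) % 360.0 < extent
            ring &= ~in_gap
            gap_arc: Optional[Tuple[float, float]] = (start, extent)
        else:
            gap_arc = None
        patch[ring] = colour
        patch[dist <= r_lumen] = LUMEN_RGB
        truth.append(GroundTruthObject(kind, (cx, cy), R,
                                       lumen_radius=r_lumen, gap_arc=gap_arc))

    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return RasterImage(pixels, "RGB"), truth


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _centroid(det) -> Tuple[float, float]:
    if isinstance(det, VesselContour):
        return det.centroid
    x, y = det
    return (float(x), float(y))


def confusion_matrix(detected: Sequence, truth: Sequence[GroundTruthObject],
                     match_radius: Optional[float] = None) -> dict:
    """Object-level confusion counts by greedy centroid matching.

    ``detected`` holds :class:`VesselContour` objects or bare ``(x, y)``
    centroids. Each detection matches at most one truth object: candidate
    pairs within ``match_radius`` of a truth centre (default: that object's
    outer radius) are assigned greedily by increasing distance. Vessels are
    the positive class, distractors the negative class:

    * TP — vessels matched by a detection; FN — vessels unmatched;
    * FP — detections matched to a distractor or to nothing;
    * TN — distractors matched by no detection.
    """
    centroids = [_centroid(d) for d in detected]
    pairs = []
    for di, (dx, dy) in enumerate(centroids):
        for tj, obj in enumerate(truth):
            limit = match_radius if match_radius is not None else obj.outer_radius
            dist = math.hypot(dx - obj.centre[0], dy - obj.centre[1])
            if dist <= limit:
                pairs.append((dist, di, tj))
    pairs.sort()
    det_used = [False] * len(centroids)
    truth_match: List[Optional[int]] = [None] * len(truth)
    for dist, di, tj in pairs:
        if det_used[di] or truth_match[tj] is not None:
            continue
        det_used[di] = True
        truth_match[tj] = di

    tp = sum(1 for obj, m in zip(truth, truth_match)
             if obj.is_vessel and m is not None)
    fn = sum(1 for obj, m in zip(truth, truth_match)
             if obj.is_vessel and m is None)
    tn = sum(1 for obj, m in zip(truth, truth_match)
             if not obj.is_vessel and m is None)
    fp_distractor = sum(1 for obj, m in zip(truth, truth_match)
                        if not obj.is_vessel and m is not None)
    fp_nothing = sum(1 for used in det_used if not used)
    return {"tp": tp, "fn": fn, "tn": tn, "fp": fp_distractor + fp_nothing}


def score_detections(detected: Sequence, truth: Sequence[GroundTruthObject],
                     match_radius: Optional[float] = None
                     ) -> Tuple[float, float]:
    """Sensitivity and specificity from :func:`confusion_matrix`.

    Returns ``(TP/(TP+FN), TN/(TN+FP))``; an empty denominator scores 1.0
    by convention (in particular, empty truth with empty detections gives
    ``(1.0, 1.0)``).
    """
    cm = confusion_matrix(detected, truth, match_radius)
    sensitivity = cm["tp"] / (cm["tp"] + cm["fn"]) if (cm["tp"] + cm["fn"]) else 1.0
    specificity = cm["tn"] / (cm["tn"] + cm["fp"]) if (cm["tn"] + cm["fp"]) else 1.0
    return (sensitivity, specificity)


def sample_benchmark_spec(seed: int, width: int = 1024, height: int = 1024
                          ) -> SceneSpec:
    """Scene parameters for one evaluation scene.

    Draws a vessel count in [10, 50] (randomly split closed/open, gap
    fractions up to 0.30) and a distractor count in [10, 30] from the scene
    seed, at the generator's default geometry. Used by the pooled
    sensitivity/specificity benchmark.
    """
    rng = np.random.default_rng(np.uint32(seed) ^ np.uint32(0x5EED))
    n_vessels = int(rng.integers(10, 51))
    n_closed = int(rng.integers(0, n_vessels + 1))
    n_distractors = int(rng.integers(10, 31))
    return SceneSpec(
        width=width, height=height,
        n_closed=n_closed, n_open=n_vessels - n_closed,
        n_distractors=n_distractors,
        gap_fraction_range=(0.10, 0.30),
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# Ground-truth serialisation
# ---------------------------------------------------------------------------

def truth_to_json(truth: Sequence[GroundTruthObject], path) -> None:
    """Write ground truth as JSON next to the generated image."""
    payload = [asdict(t) for t in truth]
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def truth_from_json(path) -> List[GroundTruthObject]:
    data = json.loads(Path(path).read_text())
    out = []
    for d in data:
        gap = d.get("gap_arc")
        out.append(GroundTruthObject(
            kind=d["kind"], centre=tuple(d["centre"]),
            outer_radius=d["outer_radius"],
            lumen_radius=d.get("lumen_radius", 0.0),
            gap_arc=tuple(gap) if gap else None,
        ))
    return out
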