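"""Raster types, image I/O and low-level binary-image operators.

Everything downstream (the HSV colour stage, the radial lumen-closing stage,
morphometry) is built from the primitives in this module: colour conversion,
channel extraction, thresholding, pixelwise logicals, binary morphology,
small-hole filling and border-following contour tracing.

Conventions (fixed for the whole package):

* images are 8-bit per channel, row-major, origin top-left;
* pixel coordinates are 0-based ``(x, y)`` = (column, row);
* HSV uses the 8-bit half-degree convention: H in [0, 179], S and V in
  [0, 255];
* binary masks hold exactly {0, 255}, 255 = foreground;
* foreground connectivity is 8, background/hole connectivity is 4;
* pixels outside the image are background for all morphology;
* the structuring element is the 3x3 square unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from PIL import Image as _PILImage
from scipy import ndimage as ndi
import tifffile as _tifffile

__all__ = [
    "RasterImage",
    "BinaryMask",
    "Contour",
    "Calibration",
    "FormatError",
    "ImageReadError",
    "load_image",
    "save_image",
    "rgb_to_hsv",
    "extract_channel",
    "threshold",
    "logical_or",
    "logical_not",
    "morph",
    "fill_small_holes",
    "find_contours",
    "signed_area",
]

# 3x3 square structuring element (8-connected); the package default.
SQUARE_3X3 = np.ones((3, 3), dtype=bool)
# 4-connected cross, used for background/hole labelling (connectivity duality).
CROSS_3X3 = ndi.generate_binary_structure(2, 1)


class ImageReadError(IOError):
    """Raised when an image file cannot be read."""


class FormatError(ValueError):
    """Raised for unsupported pixel formats (e.g. 16-bit without rescale)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class RasterImage:
    """8-bit raster image, 1 channel (grey) or 3 channels (RGB or HSV).

    ``pixels`` is a ``uint8`` array of shape ``(height, width)`` or
    ``(height, width, 3)``; ``colour_model`` is one of ``"RGB"``, ``"HSV"``,
    ``"GREY"``.
    """

    pixels: np.ndarray
    colour_model: str = "RGB"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype != np.uint8:
            raise FormatError(f"pixels must be uint8, got {self.pixels.dtype}")
        if self.pixels.ndim == 2:
            if self.colour_model != "GREY":
                raise ValueError("2-D pixel array requires colour_model='GREY'")
        elif self.pixels.ndim == 3 and self.pixels.shape[2] == 3:
            if self.colour_model not in ("RGB", "HSV"):
                raise ValueError("3-channel image must be RGB or HSV")
        else:
            raise ValueError(f"unsupported pixel shape {self.pixels.shape}")
        if self.width < 1 or self.height < 1:
            raise ValueError("image must be at least 1x1")

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else int(self.pixels.shape[2])


@dataclass
class BinaryMask:
    """Single-channel image over {0, 255}; 255 = foreground."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.pixels.dtype != np.uint8:
            raise FormatError(f"mask must be uint8, got {self.pixels.dtype}")
        bad = ~np.isin(self.pixels, (0, 255))
        if bad.any():
            raise ValueError("mask pixels must be exactly 0 or 255")

    @classmethod
    def from_bool(cls, arr: np.ndarray) -> "BinaryMask":
        return cls((np.asarray(arr, dtype=bool) * np.uint8(255)))

    def as_bool(self) -> np.ndarray:
        return self.pixels > 0

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass
class Contour:
    """Ordered closed pixel boundary.

    ``points`` is an ``(N, 2)`` integer array of ``(x, y)`` coordinates whose
    consecutive entries are 8-connected (cyclically). Orientation encodes
    topology: outer boundaries have positive shoelace signed area, holes
    negative. ``parent_id`` indexes the enclosing outer contour within the
    list returned by :func:`find_contours`.

    Components of 1-2 pixels trace to degenerate contours with fewer than 3
    points; they are preserved (the size filters downstream remove them).
    """

    points: np.ndarray
    is_hole: bool = False
    parent_id: Optional[int] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.intp).reshape(-1, 2)

    def __len__(self) -> int:
        return int(self.points.shape[0])

    @property
    def bbox(self) -> Tuple[int, int, int, int]:
        """Tight axis-aligned bounding box ``(x, y, w, h)`` in pixels."""
        xs, ys = self.points[:, 0], self.points[:, 1]
        x0, y0 = int(xs.min()), int(ys.min())
        return (x0, y0, int(xs.max()) - x0 + 1, int(ys.max()) - y0 + 1)


@dataclass(frozen=True)
class Calibration:
    """Isotropic spatial calibration in microns per pixel."""

    microns_per_pixel: float = 0.25

    def __post_init__(self) -> None:
        if not self.microns_per_pixel > 0:
            raise ValueError("microns_per_pixel must be > 0")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_SUPPORTED_SUFFIXES = {".tif", ".tiff", ".png", ".jpg", ".jpeg"}


def load_image(path, allow_16bit: bool = False) -> RasterImage:
    """Read a TIFF/PNG/JPEG file into a 3-channel RGB :class:`RasterImage`.

    Greyscale files are replicated to three identical channels. 16-bit files
    raise :class:`FormatError` unless ``allow_16bit`` is set, in which case
    they are linearly rescaled to 8-bit.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix not in _SUPPORTED_SUFFIXES:
        raise FormatError(f"unsupported image format {suffix!r}: {path}")
    try:
        if suffix in (".tif", ".tiff"):
            arr = _tifffile.imread(str(path))
        else:
            with _PILImage.open(path) as im:
                arr = np.asarray(im)
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt/unreadable
        raise ImageReadError(f"cannot read image {path}: {exc}") from exc

    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.dtype == np.uint16:
        if not allow_16bit:
            raise FormatError(
                f"{path}: 16-bit images are rejected by default; "
                "pass allow_16bit=True to rescale to 8-bit"
            )
        arr = (arr.astype(np.float64) / 257.0).round().astype(np.uint8)
    elif arr.dtype != np.uint8:
        raise FormatError(f"{path}: unsupported bit depth {arr.dtype}")
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(f"{path}: unsupported channel layout {arr.shape}")
    return RasterImage(np.ascontiguousarray(arr), "RGB")


def save_image(path, img) -> None:
    """Write a :class:`RasterImage` or :class:`BinaryMask` to disk.

    TIFF goes through :mod:`tifffile`; PNG/JPEG through Pillow.
    """
    path = Path(path)
    pixels = img.pixels
    if path.suffix.lower() in (".tif", ".tiff"):
        _tifffile.imwrite(str(path), pixels)
    else:
        _PILImage.fromarray(pixels).save(path)


# ---------------------------------------------------------------------------
# Colour conversion and channels
# ---------------------------------------------------------------------------

def rgb_to_hsv(img: RasterImage) -> RasterImage:
    """Convert an RGB image to 8-bit HSV: H in [0, 179], S and V in [0, 255].

    The brown-stain thresholds only make sense under the half-degree 8-bit
    hue convention, so it is fixed here: H = round(hue_degrees / 2) mod 180,
    S = round(255 * (max - min) / max) (0 where max = 0), V = max.
    """
    if img.colour_model != "RGB":
        raise ValueError(f"rgb_to_hsv requires RGB input, got {img.colour_model}")
    rgb = img.pixels.astype(np.float64)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    maxc = rgb.max(axis=-1)
    minc = rgb.min(axis=-1)
    delta = maxc - minc

    v = maxc
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(maxc > 0, 255.0 * delta / maxc, 0.0)
        # hue in degrees
        hue = np.zeros_like(maxc)
        nz = delta > 0
        rmax = nz & (maxc == r)
        gmax = nz & ~rmax & (maxc == g)
        bmax = nz & ~rmax & ~gmax
        hue[rmax] = 60.0 * ((g - b)[rmax] / delta[rmax])
        hue[gmax] = 60.0 * (2.0 + (b - r)[gmax] / delta[gmax])
        hue[bmax] = 60.0 * (4.0 + (r - g)[bmax] / delta[bmax])
    hue = np.mod(hue, 360.0)
    h8 = np.mod(np.rint(hue / 2.0), 180.0)
    out = np.stack(
        [h8, np.rint(s), np.rint(v)], axis=-1
    ).astype(np.uint8)
    return RasterImage(out, "HSV")


def extract_channel(img: RasterImage, channel: int) -> RasterImage:
    """Return one plane of ``img`` as a single-channel grey image."""
    if not 0 <= channel < img.n_channels:
        raise IndexError(
            f"channel {channel} out of range for {img.n_channels}-channel image"
        )
    plane = img.pixels if img.n_channels == 1 else img.pixels[:, :, channel]
    return RasterImage(np.ascontiguousarray(plane), "GREY")


# ---------------------------------------------------------------------------
# Thresholding and logicals
# ---------------------------------------------------------------------------

def threshold(img: RasterImage, t: int, inverted: bool = False) -> BinaryMask:
    """Binary threshold with strict comparison.

    ``inverted=False``: pixel > t -> 255 else 0. ``inverted=True`` is the
    complement. ``t`` is clamped to [0, 255].
    """
    if img.n_channels != 1:
        raise ValueError("threshold requires a single-channel image")
    t = int(min(max(t, 0), 255))
    above = img.pixels > t
    fg = ~above if inverted else above
    return BinaryMask.from_bool(fg)


def logical_or(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    """Pixelwise union of two masks of equal dimensions."""
    if a.pixels.shape != b.pixels.shape:
        raise ValueError(
            f"mask dimensions differ: {a.pixels.shape} vs {b.pixels.shape}"
        )
    return BinaryMask(np.maximum(a.pixels, b.pixels))


def logical_not(a: BinaryMask) -> BinaryMask:
    """Pixelwise complement over {0, 255}."""
    return BinaryMask(np.uint8(255) - a.pixels)


# ---------------------------------------------------------------------------
# Morphology
# ---------------------------------------------------------------------------

def morph(
    mask: BinaryMask,
    op: str,
    iterations: int = 1,
    se: Optional[np.ndarray] = None,
) -> BinaryMask:
    """Binary erosion or dilation; ``iterations=0`` is the identity.

    ``k`` iterations apply the structuring element ``k`` times. Out-of-image
    pixels are background, so erosion eats the border ring and dilation never
    grows from outside.
    """
    if op not in ("erode", "dilate"):
        raise ValueError(f"op must be 'erode' or 'dilate', got {op!r}")
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        return BinaryMask(mask.pixels.copy())
    se = SQUARE_3X3 if se is None else np.asarray(se, dtype=bool)
    fg = mask.as_bool()
    if op == "erode":
        out = ndi.binary_erosion(fg, structure=se, iterations=iterations,
                                 border_value=0)
    else:
        out = ndi.binary_dilation(fg, structure=se, iterations=iterations,
                                  border_value=0)
    return BinaryMask.from_bool(out)


def fill_small_holes(mask: BinaryMask, max_hole_px: int) -> BinaryMask:
    """Fill enclosed background components strictly smaller than ``max_hole_px``.

    A hole is a 4-connected background component that does not touch the image
    border. Holes of area >= ``max_hole_px`` are left open.
    """
    if max_hole_px < 0:
        raise ValueError("max_hole_px must be >= 0")
    fg = mask.as_bool()
    bg_labels, n = ndi.label(~fg, structure=CROSS_3X3)
    if n == 0 or max_hole_px == 0:
        return BinaryMask(mask.pixels.copy())
    border = np.zeros_like(fg)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    touching = np.unique(bg_labels[border & ~fg])
    areas = np.bincount(bg_labels.ravel(), minlength=n + 1)
    fill = np.zeros(n + 1, dtype=bool)
    fill[1:] = areas[1:] < max_hole_px
    fill[touching] = False
    return BinaryMask.from_bool(fg | fill[bg_labels])


# ---------------------------------------------------------------------------
# Contour tracing
# ---------------------------------------------------------------------------

def signed_area(points: np.ndarray) -> float:
    """Shoelace signed area of a closed polygon given as (N, 2) (x, y)."""
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 2)
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


# Moore neighbourhood scanned clockwise on screen starting from West,
# as (dr, dc) with rows growing downward.
_MOORE = np.array(
    [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)],
    dtype=np.intp,
)
_MOORE_INDEX = {(int(dr), int(dc)): i for i, (dr, dc) in enumerate(_MOORE)}


def _moore_trace(region: np.ndarray) -> np.ndarray:
    """Moore-neighbour border following on a padded boolean array.

    Returns boundary pixels as an (N, 2) array of (row, col), a closed
    8-connected cycle. Uses Jacob's stopping criterion (stop on re-entering
    the start pixel from the start direction). Single pixels give N = 1.
    """
    rows, cols = np.nonzero(region)
    # topmost then leftmost (nonzero is row-major)
    start = (int(rows[0]), int(cols[0]))
    # backtrack: the background pixel scanned before finding start (its West)
    backtrack = (start[0], start[1] - 1)

    path = [start]
    cur = start
    first_move = None
    # scan clockwise from the neighbour after backtrack
    for _ in range(4 * region.size + 8):
        b_idx = _MOORE_INDEX[(backtrack[0] - cur[0], backtrack[1] - cur[1])]
        nxt = None
        for j in range(1, 9):
            dr, dc = _MOORE[(b_idx + j) % 8]
            cand = (cur[0] + int(dr), cur[1] + int(dc))
            if region[cand]:
                nxt = cand
                break
            backtrack = cand
        if nxt is None:  # isolated pixel
            break
        move = (nxt[0] - cur[0], nxt[1] - cur[1])
        if first_move is None:
            first_move = move
            first_from = cur
        elif cur == first_from and move == first_move and len(path) > 1:
            path.pop()  # the revisited start was appended; drop duplicate
            break
        cur = nxt
        path.append(cur)
    else:  # pragma: no cover - safety cap
        raise RuntimeError("contour tracing failed to terminate")
    if len(path) > 1 and path[-1] == path[0]:
        path.pop()
    return np.array(path, dtype=np.intp)


def _trace_region(region: np.ndarray, origin_rc: Tuple[int, int]) -> np.ndarray:
    """Trace a boolean subarray's outer boundary; return (N, 2) (x, y) global."""
    padded = np.zeros((region.shape[0] + 2, region.shape[1] + 2), dtype=bool)
    padded[1:-1, 1:-1] = region
    rc = _moore_trace(padded)
    rc -= 1  # unpad
    xy = np.empty_like(rc)
    xy[:, 0] = rc[:, 1] + origin_rc[1]
    xy[:, 1] = rc[:, 0] + origin_rc[0]
    return xy


def _orient(points: np.ndarray, positive: bool) -> np.ndarray:
    a = signed_area(points)
    if (a < 0) == positive and a != 0:
        return points[::-1].copy()
    return points


def find_contours(
    source,
    edge_mode: str = "threshold",
    canny_low: float = 50.0,
    canny_high: float = 150.0,
) -> List[Contour]:
    """Border-following trace of all outer boundaries and first-level holes.

    ``edge_mode="threshold"`` takes a :class:`BinaryMask`. With
    ``edge_mode="canny"`` the caller supplies the pre-threshold grey
    :class:`RasterImage`; Canny edges (aperture 3, hysteresis thresholds
    ``canny_low``/``canny_high`` on the 0-255 scale) are binarised first.

    Each 8-connected foreground component yields exactly one outer contour
    (positive orientation); each of its 4-connected enclosed holes yields one
    hole contour (negative orientation, traced along the hole pixels) with
    ``parent_id`` pointing at the outer contour's index in the returned list.
    An empty mask returns an empty list.
    """
    if edge_mode == "canny":
        from skimage import feature as _skfeature

        if not isinstance(source, RasterImage) or source.n_channels != 1:
            raise ValueError("canny mode requires a single-channel RasterImage")
        edges = _skfeature.canny(
            source.pixels.astype(np.float64),
            sigma=1.0,
            low_threshold=canny_low,
            high_threshold=canny_high,
        )
        mask = BinaryMask.from_bool(edges)
    elif edge_mode == "threshold":
        if not isinstance(source, BinaryMask):
            raise ValueError("threshold mode requires a BinaryMask")
        mask = source
    else:
        raise ValueError(f"unknown edge_mode {edge_mode!r}")

    fg = mask.as_bool()
    labels, n = ndi.label(fg, structure=SQUARE_3X3)
    contours: List[Contour] = []
    if n == 0:
        return contours
    slices = ndi.find_objects(labels)
    for comp_id, sl in enumerate(slices, start=1):
        region = labels[sl] == comp_id
        origin = (sl[0].start, sl[1].start)
        outer = _orient(_trace_region(region, origin), positive=True)
        parent_index = len(contours)
        contours.append(Contour(outer, is_hole=False, parent_id=None))
        # holes: enclosed 4-connected background inside this component
        filled = ndi.binary_fill_holes(region, structure=CROSS_3X3)
        holes = filled & ~region
        if holes.any():
            hlabels, hn = ndi.label(holes, structure=CROSS_3X3)
            hslices = ndi.find_objects(hlabels)
            for hid, hsl in enumerate(hslices, start=1):
                hregion = hlabels[hsl] == hid
                horigin = (origin[0] + hsl[0].start, origin[1] + hsl[1].start)
                hpts = _orient(_trace_region(hregion, horigin), positive=False)
                contours.append(
                    Contour(hpts, is_hole=True, parent_id=parent_index)
                )
    return contours


def rasterise_contour(
    contour: Contour, shape: Tuple[int, int], fill: bool = True
) -> BinaryMask:
    """Draw a contour onto a blank ``(height, width)`` canvas.

    With ``fill=True`` the enclosed interior is filled (4-connected hole
    filling, the dual of the 8-connected boundary).
    """
    canvas = np.zeros(shape, dtype=bool)
    pts = contour.points
    canvas[pts[:, 1], pts[:, 0]] = True
    if fill:
        canvas = ndi.binary_fill_holes(canvas, structure=CROSS_3X3)
    return BinaryMask.from_bool(canvas)
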