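"""Unit and property tests for the raster primitives."""

from __future__ import annotations

import colorsys

import numpy as np
import pytest
import tifffile
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from PIL import Image
from scipy import ndimage as ndi

from angiopath import (
    BinaryMask,
    Contour,
    FormatError,
    RasterImage,
    extract_channel,
    fill_small_holes,
    find_contours,
    load_image,
    logical_not,
    logical_or,
    morph,
    rgb_to_hsv,
    threshold,
)
from angiopath.imaging_core import rasterise_contour, signed_area

from conftest import draw_annulus, draw_disc, random_blob_mask


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

class TestLoadImage:
    def test_rgb_tiff_roundtrip(self, tmp_path, rng):
        arr = rng.integers(0, 256, size=(21, 33, 3), dtype=np.uint8)
        p = tmp_path / "img.tif"
        tifffile.imwrite(p, arr)
        img = load_image(p)
        assert img.colour_model == "RGB"
        np.testing.assert_array_equal(img.pixels, arr)

    def test_grey_png_replicated_to_rgb(self, tmp_path, rng):
        arr = rng.integers(0, 256, size=(15, 17), dtype=np.uint8)
        p = tmp_path / "img.png"
        Image.fromarray(arr).save(p)
        img = load_image(p)
        assert img.pixels.shape == (15, 17, 3)
        for c in range(3):
            np.testing.assert_array_equal(img.pixels[:, :, c], arr)

    def test_16bit_rejected_then_rescaled(self, tmp_path):
        arr = np.full((8, 8), 65535, dtype=np.uint16)
        p = tmp_path / "img.tif"
        tifffile.imwrite(p, arr)
        with pytest.raises(FormatError):
            load_image(p)
        img = load_image(p, allow_16bit=True)
        assert img.pixels.max() == 255

    def test_missing_file_raises_with_path(self, tmp_path):
        with pytest.raises(OSError):
            load_image(tmp_path / "nope.tif")


# ---------------------------------------------------------------------------
# Colour conversion
# ---------------------------------------------------------------------------

class TestRgbToHsv:
    @pytest.mark.parametrize(
        "rgb,expected",
        [
            ((255, 0, 0), (0, 255, 255)),  # hue origin
            ((128, 128, 128), (0, 0, 128)),  # zero saturation
        ],
    )
    def test_primary_values(self, rgb, expected):
        img = RasterImage(np.full((2, 2, 3), rgb, dtype=np.uint8), "RGB")
        hsv = rgb_to_hsv(img)
        assert tuple(hsv.pixels[0, 0]) == expected

    @pytest.mark.parametrize(
        "rgb", [(150, 90, 40), (42, 120, 200), (245, 225, 230), (10, 10, 11)]
    )
    def test_matches_closed_form(self, rgb):
        """Independent oracle: the standard RGB->HSV closed form (colorsys),
        quantised to the 8-bit half-degree convention."""
        h, s, v = colorsys.rgb_to_hsv(*(c / 255.0 for c in rgb))
        expected = (
            int(round(h * 360.0 / 2.0)) % 180,
            int(round(s * 255.0)),
            int(round(v * 255.0)),
        )
        img = RasterImage(np.full((1, 1, 3), rgb, dtype=np.uint8), "RGB")
        assert tuple(rgb_to_hsv(img).pixels[0, 0]) == expected

    def test_dab_brown_lands_in_brown_band(self):
        # the reference DAB palette pixel must satisfy H <= 20, S > 30
        img = RasterImage(np.full((1, 1, 3), (150, 90, 40), dtype=np.uint8))
        h, s, v = rgb_to_hsv(img).pixels[0, 0]
        assert h <= 20 and s > 30
        assert (h, s, v) == (14, 187, 150)

    def test_requires_rgb(self):
        grey = RasterImage(np.zeros((4, 4), dtype=np.uint8), "GREY")
        with pytest.raises(ValueError):
            rgb_to_hsv(grey)


class TestExtractChannel:
    def test_planes_and_identity(self, rng):
        arr = rng.integers(0, 256, size=(9, 9, 3), dtype=np.uint8)
        img = RasterImage(arr, "RGB")
        np.testing.assert_array_equal(extract_channel(img, 1).pixels,
                                      arr[:, :, 1])
        grey = extract_channel(img, 0)
        np.testing.assert_array_equal(extract_channel(grey, 0).pixels,
                                      grey.pixels)

    def test_out_of_range(self):
        img = RasterImage(np.zeros((4, 4, 3), dtype=np.uint8), "RGB")
        with pytest.raises(IndexError):
            extract_channel(img, 3)


# ---------------------------------------------------------------------------
# Threshold and logicals
# ---------------------------------------------------------------------------

class TestThreshold:
    def test_strict_inequality_at_boundary(self):
        img236 = RasterImage(np.full((5, 5), 236, dtype=np.uint8), "GREY")
        img237 = RasterImage(np.full((5, 5), 237, dtype=np.uint8), "GREY")
        assert not threshold(img236, 236).as_bool().any()
        assert threshold(img237, 236).as_bool().all()

    def test_inverted_is_complement(self, rng):
        img = RasterImage(
            rng.integers(0, 256, size=(12, 12), dtype=np.uint8), "GREY")
        for t in (0, 30, 128, 255):
            np.testing.assert_array_equal(
                threshold(img, t, inverted=True).pixels,
                logical_not(threshold(img, t, inverted=False)).pixels,
            )


class TestLogicals:
    def test_or_against_pixel_loop_oracle(self, rng):
        a = BinaryMask.from_bool(rng.random((10, 11)) > 0.5)
        b = BinaryMask.from_bool(rng.random((10, 11)) > 0.5)
        got = logical_or(a, b).pixels
        for i in range(10):
            for j in range(11):
                assert got[i, j] == max(a.pixels[i, j], b.pixels[i, j])

    def test_algebraic_identities(self, rng):
        zeros = BinaryMask(np.zeros((8, 8), dtype=np.uint8))
        m = BinaryMask.from_bool(rng.random((8, 8)) > 0.4)
        n = BinaryMask.from_bool(rng.random((8, 8)) > 0.6)
        np.testing.assert_array_equal(logical_or(zeros, m).pixels, m.pixels)
        np.testing.assert_array_equal(
            logical_not(logical_not(m)).pixels, m.pixels)
        np.testing.assert_array_equal(
            logical_or(m, n).pixels, logical_or(n, m).pixels)
        np.testing.assert_array_equal(logical_or(m, m).pixels, m.pixels)

    def test_dimension_mismatch(self):
        a = BinaryMask(np.zeros((4, 4), dtype=np.uint8))
        b = BinaryMask(np.zeros((4, 5), dtype=np.uint8))
        with pytest.raises(ValueError):
            logical_or(a, b)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        grey=hnp.arrays(np.uint8, hnp.array_shapes(min_dims=2, max_dims=2,
                                                   max_side=12)),
        t=st.integers(0, 255),
    )
    def test_pixelwise_algebra_holds_for_arbitrary_images(self, grey, t):
        """threshold/NOT/OR form the expected Boolean algebra on any image."""
        img = RasterImage(grey, "GREY")
        m = threshold(img, t)
        assert np.array_equal(threshold(img, t, inverted=True).pixels,
                              logical_not(m).pixels)
        assert np.array_equal(logical_or(m, m).pixels, m.pixels)
        assert np.array_equal(
            logical_or(m, logical_not(m)).pixels,
            np.full_like(m.pixels, 255))


# ---------------------------------------------------------------------------
# Morphology
# ---------------------------------------------------------------------------

def _minmax_oracle(fg: np.ndarray, op: str, iterations: int) -> np.ndarray:
    """Brute-force 3x3 min/max filter with background padding."""
    out = fg.copy()
    for _ in range(iterations):
        padded = np.zeros((out.shape[0] + 2, out.shape[1] + 2), dtype=bool)
        padded[1:-1, 1:-1] = out
        nxt = np.zeros_like(out)
        for i in range(out.shape[0]):
            for j in range(out.shape[1]):
                window = padded[i : i + 3, j : j + 3]
                nxt[i, j] = window.all() if op == "erode" else window.any()
        out = nxt
    return out


class TestMorph:
    def test_matches_minmax_oracle_on_random_masks(self, rng):
        for _ in range(20):
            mask = random_blob_mask(rng, shape=(18, 18))
            for op in ("erode", "dilate"):
                for k in (1, 2):
                    got = morph(mask, op, k).as_bool()
                    np.testing.assert_array_equal(
                        got, _minmax_oracle(mask.as_bool(), op, k))

    def test_border_policy_erodes_edge(self):
        full = BinaryMask(np.full((7, 7), 255, dtype=np.uint8))
        er = morph(full, "erode", 1).as_bool()
        assert er[1:-1, 1:-1].all()
        assert not er[0].any() and not er[-1].any()
        assert not er[:, 0].any() and not er[:, -1].any()

    def test_dilate_single_pixel_makes_3x3_block(self):
        m = np.zeros((7, 7), dtype=np.uint8)
        m[3, 3] = 255
        di = morph(BinaryMask(m), "dilate", 1).as_bool()
        assert di[2:5, 2:5].all() and di.sum() == 9

    def test_zero_iterations_is_identity(self, rng):
        mask = random_blob_mask(rng)
        np.testing.assert_array_equal(morph(mask, "erode", 0).pixels,
                                      mask.pixels)

    def test_erosion_dilation_inclusion(self, rng):
        for k in (0, 1, 3):
            mask = random_blob_mask(rng)
            fg = mask.as_bool()
            er = morph(mask, "erode", k).as_bool()
            di = morph(mask, "dilate", k).as_bool()
            assert (er <= fg).all() and (fg <= di).all()

    def test_open_removes_thin_bridge(self):
        m = np.zeros((20, 40), dtype=bool)
        m[5:15, 3:13] = True
        m[5:15, 27:37] = True
        m[9:11, 13:27] = True  # 2-px bridge
        opened = morph(morph(BinaryMask.from_bool(m), "erode", 1),
                       "dilate", 1).as_bool()
        _, n = ndi.label(opened, structure=np.ones((3, 3)))
        assert n == 2


class TestFillSmallHoles:
    @staticmethod
    def _ring_with_hole(hole_w, hole_h):
        m = np.ones((hole_h + 10, hole_w + 10), dtype=bool)
        m[5 : 5 + hole_h, 5 : 5 + hole_w] = False
        return BinaryMask.from_bool(m)

    def test_strict_inequality_at_400(self):
        just_under = self._ring_with_hole(21, 19)  # 399 px
        at_limit = self._ring_with_hole(20, 20)  # 400 px
        assert fill_small_holes(just_under, 400).as_bool().all()
        filled = fill_small_holes(at_limit, 400)
        np.testing.assert_array_equal(filled.pixels, at_limit.pixels)

    def test_border_touching_background_untouched(self):
        m = np.zeros((10, 10), dtype=bool)
        m[3:7, 3:7] = True
        out = fill_small_holes(BinaryMask.from_bool(m), 1000)
        np.testing.assert_array_equal(out.as_bool(), m)

    def test_zero_max_is_identity_and_idempotent_and_monotone(self, rng):
        for _ in range(10):
            mask = random_blob_mask(rng, shape=(25, 25))
            np.testing.assert_array_equal(
                fill_small_holes(mask, 0).pixels, mask.pixels)
            once = fill_small_holes(mask, 12)
            twice = fill_small_holes(once, 12)
            np.testing.assert_array_equal(once.pixels, twice.pixels)
            assert (mask.as_bool() <= once.as_bool()).all()


# ---------------------------------------------------------------------------
# Contour tracing
# ---------------------------------------------------------------------------

def _flood_fill_component_count(fg: np.ndarray) -> int:
    """Independent 8-connected component count by explicit BFS."""
    seen = np.zeros_like(fg, dtype=bool)
    count = 0
    h, w = fg.shape
    for si in range(h):
        for sj in range(w):
            if not fg[si, sj] or seen[si, sj]:
                continue
            count += 1
            stack = [(si, sj)]
            seen[si, sj] = True
            while stack:
                i, j = stack.pop()
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        ni, nj = i + di, j + dj
                        if (0 <= ni < h and 0 <= nj < w
                                and fg[ni, nj] and not seen[ni, nj]):
                            seen[ni, nj] = True
                            stack.append((ni, nj))
    return count


class TestFindContours:
    def test_solid_square(self):
        m = np.zeros((14, 14), dtype=bool)
        m[2:12, 2:12] = True
        cs = find_contours(BinaryMask.from_bool(m))
        assert len(cs) == 1 and not cs[0].is_hole
        assert cs[0].bbox == (2, 2, 10, 10)

    def test_annulus_topology_and_orientation(self, annulus_mask):
        cs = find_contours(annulus_mask)
        outers = [c for c in cs if not c.is_hole]
        holes = [c for c in cs if c.is_hole]
        assert len(outers) == 1 and len(holes) == 1
        assert holes[0].parent_id == cs.index(outers[0])
        assert signed_area(outers[0].points) > 0
        assert signed_area(holes[0].points) < 0

    def test_consecutive_points_8_connected(self, annulus_mask):
        for c in find_contours(annulus_mask):
            d = np.abs(np.diff(np.vstack([c.points, c.points[:1]]), axis=0))
            assert (d.max(axis=1) == 1).all()

    def test_empty_mask_empty_list(self):
        assert find_contours(BinaryMask(np.zeros((6, 6), dtype=np.uint8))) == []

    def test_outer_count_matches_flood_fill_oracle(self, rng):
        for _ in range(20):
            mask = random_blob_mask(rng, shape=(30, 30))
            outers = [c for c in find_contours(mask) if not c.is_hole]
            assert len(outers) == _flood_fill_component_count(mask.as_bool())

    def test_rasterise_round_trip(self, rng):
        """Filling each outer contour reproduces the filled components."""
        for _ in range(20):
            mask = random_blob_mask(rng, shape=(30, 30))
            fg = mask.as_bool()
            recon = np.zeros_like(fg)
            for c in find_contours(mask):
                if not c.is_hole:
                    recon |= rasterise_contour(c, fg.shape).as_bool()
            labels, n = ndi.label(fg, structure=np.ones((3, 3)))
            filled = np.zeros_like(fg)
            for i in range(1, n + 1):
                filled |= ndi.binary_fill_holes(
                    labels == i, structure=ndi.generate_binary_structure(2, 1))
            np.testing.assert_array_equal(recon, filled)

    def test_canny_mode_traces_disc_edge(self):
        grey = np.zeros((60, 60), dtype=np.uint8)
        grey[draw_disc((60, 60), (30, 30), 15)] = 220
        cs = find_contours(RasterImage(grey, "GREY"), edge_mode="canny")
        assert len(cs) >= 1
        # edge sits near the disc boundary
        pts = np.vstack([c.points for c in cs])
        dist = np.hypot(pts[:, 0] - 30, pts[:, 1] - 30)
        assert abs(np.median(dist) - 15) < 3

    def test_canny_mode_rejects_mask_input(self, annulus_mask):
        with pytest.raises(ValueError):
            find_contours(annulus_mask, edge_mode="canny")
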