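# Methods

## Model and assumptions

The segmenter targets brightfield IHC images in which vessel endothelium is
DAB-brown, vascular lumens are bright (near-white), and background tissue
is pale. It assumes 8-bit RGB input; there is no stain normalisation or
colour deconvolution, so the fixed colour thresholds presume a reasonably
standard DAB/counterstain appearance.

Two detection routes run in sequence:

1. **Colour stage.** Brown selection is a pure pixel classifier in HSV:
   foreground iff S > `s_threshold` and H ≤ `h_threshold`. It is composed
   from an inverted threshold on S (removes unsaturated background), a
   plain threshold on H (removes high-hue colours such as haematoxylin
   blue), OR, and NOT — the composition matters only in that each binary
   primitive is independently testable. Erosion (2) then dilation (4)
   removes specks and joins nearby stained fragments; border-following
   contour tracing recovers each stained object with its holes, and the
   largest hole of each object is taken as its lumen. The size filter
   drops small objects (macrophages).
2. **Radial stage.** Bright-lumen candidates come from the green channel
   (lumens are bright in all channels; one channel is enough and cheap).
   The erode/dilate/fill/erode sequence removes bright noise, fills small
   dark inclusions inside lumens (< `max_hole_px`), and separates the
   lumen boundary from the membrane. Each candidate boundary point probes
   outward along its normal for membrane pixels in the **raw** (pre-cleanup)
   brown mask — cleanup could bridge exactly the gaps this stage must see.
   Validation is by the fraction of boundary points with a membrane hit.

Both stages can detect the same vessel; deduplication keeps the
colour-stage detection (closed colour evidence is stronger). Because a
radial detection traces the lumen while a colour detection traces the
outer wall, duplicate pairs are concentric with very different bbox areas;
the suppression rule is therefore bbox IoU > 0.5 **or** bbox containment
> 0.8 of the smaller detection inside the kept one. IoU alone misses
thick-walled duplicates and, on the synthetic benchmark, roughly one
duplicate per two vessels would survive as a false positive.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `hsv.s_threshold` | 30 | 8-bit S | min saturation of stain |
| `hsv.h_threshold` | 20 | half-degrees | max hue of the brown band |
| `hsv.erode_iters` / `dilate_iters` | 2 / 4 | iterations | speck removal / joining |
| `hsv.min_contour_points` | 6 | points | size filter (perimeter) |
| `hsv.min_bbox_px` | 20 | px | size filter (both bbox sides, strict >) |
| `hsv.filter_combinator` | `and` | — | see below |
| `radial.green_threshold` | 236 | 8-bit | min lumen brightness |
| `radial.erode_iters` / `dilate_iters` | 3 / 2 | iterations | lumen cleanup |
| `radial.max_hole_px` | 400 | px | fill dark inclusions strictly smaller |
| `radial.second_erode_iters` | 1 | iterations | membrane/lumen separation |
| `radial.probe_min_px` / `probe_max_px` | 2 / 30 | px | normal probe reach (7.5 µm at 0.25 µm/px — a plausible endothelium offset) |
| `radial.base_ratio` | 0.60 | fraction | validity threshold |
| `radial.small_contour_points` / `small_ratio` | 100 / 0.80 | points / fraction | stricter threshold for short contours |
| `calibration.microns_per_pixel` | 0.25 | µm/px | 40x brightfield ballpark; always overridable, px values always emitted |

Fixed conventions: HSV on the 8-bit half-degree scale (H ∈ [0,179] — the
default thresholds only make sense there); strict `>` comparisons in all
thresholds and size filters; 3×3 square structuring element everywhere;
out-of-image pixels are background; foreground connectivity 8, hole
connectivity 4; outer contours carry positive shoelace orientation, holes
negative.

Design choices that were genuinely open:

* **Size-filter combinator.** Read literally as "more than 6 boundary
  points OR bbox > 20 px", the filter can never remove a macrophage-sized
  blob (any blob over ~2 px across has > 6 boundary points), defeating its
  stated purpose. The default is therefore `and`; `or` is retained as a
  config option for literal fidelity.
* **"Overall size" of 6 pixels** is interpreted as contour point count
  (alternatives: area, bbox diagonal); the bbox rule as both sides
  strictly greater than 20 px.
* **Size-adjusted validity threshold** is a two-level step function
  (short contours need 0.80 coverage, others 0.60). Shorter lumen contours
  have fewer probe points and more digitisation noise per point, so a
  stricter level is applied rather than a continuous ramp, which would add
  a free slope parameter with no data to fit it.
* **Closing offset.** Accepted lumens are dilated back by the cleanup's
  net erosion (3 − 2 + 1 = 2 px by default) so the emitted contour sits at
  the lumen boundary rather than 2 px inside it.
* **Normal estimation** uses a cyclic central difference with half-window
  k = 2 points; k = 1 is dominated by the 8-direction quantisation of
  digital curves (normals off by up to 45°), while k = 2 keeps normals
  within ~15° of the true radial direction on digital circles.

## Morphometry estimators

Shape factors are the standard ones: aspect = max(w,h)/min(w,h),
roundness = 4πA/P² (isoperimetric quotient), perimeter ratio =
convex-hull perimeter / contour perimeter.

Raw polygon formulas are biased on traced pixel boundaries: the shoelace
area of a pixel-centre polygon under-covers the digital region by about
half a pixel per boundary step (−4.5% for a disc of radius 20), and raw
chain length over-estimates smooth perimeters by 5–8%, pushing disc
roundness down to ~0.87. Contours whose edges are all unit chain steps
(i.e. every traced boundary) are therefore measured with the standard
bias-corrected digital estimators:

* area: shoelace + N/2 + 1 — by Pick's theorem exactly the enclosed pixel
  count; within 0.3% of πr² for discs with r ≥ 20 px;
* perimeter: weighted chain length, 0.948 per straight step and 1.340 per
  diagonal step (Vossepoel–Smeulders), within ~0.5% of 2πr;
* bbox extents: pixel extents (max − min + 1).

Sparse vertex polygons (anything with a non-unit edge) are measured
exactly: shoelace area, Euclidean edge lengths, geometric extents. A
10×10 square polygon thus has area 100 and roundness π/4 ≈ 0.785, while a
traced digital disc has roundness 1.00–1.01. Dimensionless factors carry
a digitisation slack of ε = 0.05 (roundness and perimeter ratio may reach
1 + ε).

Vascular density is reported both as vessel count per mm² (classic
microvessel density) and as vessel area fraction, since either may be
wanted and neither definition is canonical.

Degenerate inputs: contours with fewer than 3 points raise a measurement
error; collinear point sets fall back to a segment-length hull perimeter;
ties in the greedy scorer are broken by (distance, detection index, truth
index), making scoring order-independent.

## Synthetic scenes: what they do and do not show

The generator draws brown annuli (ring thickness 6–12 px, outer radius
15–40 px) with near-white lumens on a pale pink background, erases an arc
of 10–30% of the circumference for open vessels, adds solid brown blobs of
6–14 px diameter as macrophage surrogates, applies small per-object colour
jitter (±8 per channel, staying inside the brown band) and Gaussian pixel
noise (σ = 4 grey levels). Objects are placed by rejection sampling with a
14 px clearance. Everything is driven by one seed; scenes are
bit-reproducible.

This emulates the *geometry and colour logic* of the assay — closed and
broken stained rings, bright lumens, small stained distractors — and
therefore exercises every branch of both stages with known ground truth.
It does **not** model nuclei and stroma texture, stain gradients, uneven
illumination, touching vessels, or non-annular vessel cross-sections;
passing the synthetic benchmark shows the algorithm is implemented
correctly and is internally consistent, not that these performance figures
transfer to real slides.

Specificity needs true negatives, which are ill-defined at pixel level for
object detection; the distractor blobs serve as the negative class, and
matching is greedy nearest-centroid within each truth object's outer
radius (IoU matching would add nothing for near-circular objects).

## Problem sizes

The pooled benchmark (also used by `scripts/acceptance.py`) runs 20 scenes
of 1024×1024 px with 10–50 vessels and 10–30 distractors each — roughly
600 vessels and 400 negatives pooled — in about a minute on one CPU.
Property sweeps (filter monotonicity, determinism) use 512×512 px scenes
with ~7 vessels each, which is enough to exercise both stages per scene.

## Known limitations

* Fixed colour thresholds; stains that shift the brown band (or heavy
  counterstain) need per-assay configuration.
* Whole-image processing only; no tiling or pyramidal (whole-slide)
  reading.
* A vessel whose lumen is dimmer than the green threshold and whose wall
  is broken is invisible to both stages by construction.
* The radial stage validates each lumen independently; two lumens inside
  one membrane (e.g. a folded vessel) are emitted as two vessels.
* 16-bit inputs are rejected by default (the pipeline is 8-bit
  throughout); an opt-in linear rescale is provided.
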