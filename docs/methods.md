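# Methods

This note records the model, the numerical choices, and the reasoning behind
the design decisions — what the code computes and why, and what the synthetic
validation does and does not establish.

## Coordinate and landmark conventions

Image coordinates are 0-based pixel centers; `x` is the column, `y` the row
(increasing downward). Rotations are in degrees, mathematically positive in
`(x, y)` — on screen, with `y` down, a positive angle turns clockwise.

A vertebral body is represented by its four corner points: 1 = anterior-
superior, 2 = posterior-superior, 3 = anterior-inferior, 4 = posterior-
inferior, so the diagonals are (1,4) and (2,3) and their intersection is the
geometric center. The *midline* joins the posterior-edge midpoint to the
anterior-edge midpoint and therefore points anteriorly. Because "anterior" is
carried by the corner labels rather than an image axis, left- and right-facing
sagittal views need no orientation flag: label the corners anatomically and
every sign convention follows. A pair whose midlines point in opposing
directions (anterior disagreement > 90°) is rejected as inconsistently
labelled; this also guarantees the translation measure is exactly antisymmetric
under swapping upper and lower.

## Intervertebral measures

For an adjacent pair (upper, lower):

* **Translation** — construct both midlines, take the bisector of the acute
  angle between them (for parallel midlines: the parallel line midway between
  them, the continuous limit), orient it anteriorly (positive dot product with
  the mean midline direction), drop a perpendicular from each geometric center,
  and report the signed distance between the two feet along the bisector.
  Positive = the upper body sits anterior to the lower. Measuring along the
  bisector makes the value invariant to a *common* tilt of both bodies; a
  *relative* tilt swings the bisector by half the angle and couples the center
  separation into the reading (see the worked example in the README) — this is
  a property of the construction, not an artifact.
* **Relative rotation** — the acute angle between the midlines, in [0, 90]°.
* **Cobb angle** — the angle between the perpendiculars erected on the two
  midlines. In the plane this equals the relative rotation identically; the
  two are implemented as separate code paths and asserted equal (to 1e-9°) in
  the tests as a cross-check. A signed variant (sign of the upper-vs-lower
  rotation) is available behind a flag; the default report is unsigned.

No depth normalization (dividing translation by mean vertebral depth) and no
millimetre calibration are applied; the measures are in pixels and degrees. An
optional `mm_per_pixel` factor scales translations when the acquisition scale
is known.

## Tracking model

The template is the binary "vertebra section" captured once from frame 0: the
tracking substrate (Otsu region map by default, Canny edge map with
`match_on=edges`) masked by the expert contour polygon, or by the corner quad
when no contour was drawn. The template is rigid; only its pose accumulates —
no appearance update from later frames, so drift can only come from pose error,
never from template contamination.

Coincidence of a posed template with the next frame's binary map is the
fraction of template one-pixels that land on foreground, with nearest-neighbour
sampling (`floor(v + 0.5)`, which commutes with integer shifts) and off-image
samples counting as misses. Every score is an exact rational `hits / N`, which
makes brute-force equivalence testable exactly.

The per-frame search is exhaustive over a symmetric grid, theta outer, then dy,
then dx, each from negative to positive; ties prefer the least motion (smaller
|dθ|, |dy|, |dx|, then first encountered) — the prior that consecutive
fluoroscopic frames differ little. The rotation pivot is the geometric center
of the current propagated quad, decoupling the rotation range from the
translation range. The implementation vectorizes over shifts and, for integral
shift grids, evaluates all shifts at once as an exact integer cross-correlation
(FFT result rounded back to integer counts; values are orders of magnitude
below the float64 integer limit). Both paths are extensionally identical to the
naive triple loop, including tie-breaks, and are regression-tested against it
on hundreds of randomized instances.

A best score below the lost-track floor (default 0.2) raises a loud error
naming the vertebra and frame; in the pipeline the remaining vertebrae continue
and the failure is reported in the summary.

### Grid resolution: why 1° and 1 px

Defaults: `theta_max` 10°, `theta_step` 1°, `shift_max` 15 px, `shift_step`
1 px, all configurable. The 1 px shift step is the natural quantum of a binary
raster. The rotation step was set by a discrimination analysis: rotating a
w×h body by δ about its center sweeps corner wedges of roughly (w²+h²)·δ/4
pixels, while nearest-neighbour rounding of the ~2(w+h) boundary pixels
fluctuates with a standard deviation of a few pixels between neighbouring
poses. For a 100×56 px body the 0.5° wedge (~29 px) is only ~3σ above that
rounding noise and sub-degree candidates frequently beat the true pose, whereas
at 1° the margin is ~5σ and recovery of on-grid motion is exact in every
tested cell (540/540 over 30 seeds). A finer grid therefore adds cost but not
resolution; sub-degree accuracy would require grayscale (not binary) matching
or much larger bodies.

## Preprocessing

Order: contrast normalization (linear stretch to [0, 255], computed as
`(v − min)·255/(max − min)` with exact integer numerators, truncated to uint8;
constant images pass through with a warning) → histogram equalization (classic
256-bin CDF remap, monotone by construction) → Canny (scikit-image, σ = 1.4,
hysteresis thresholds default 50/150 on the 0–255 gradient scale; the image is
anchored at its minimum first so a global brightness offset leaves the result
bit-identical) → binarization (`pixel = 1 iff intensity ≥ t`).

The *edge* products (annotation snapping, `match_on=edges`) come from the
equalized image. The *region* maps the tracker matches on threshold the
**normalized** image instead: equalization flattens the histogram by design,
which destroys the bone/soft-tissue bimodality Otsu needs — on noisy frames
Otsu-on-equalized marks half the background as foreground and the match
degenerates. Otsu's threshold is adapted to the ≥ rule (the smallest intensity
strictly above scikit-image's `>`-convention value), and a fixed numeric
threshold can be configured instead.

Expert contours may not leave the detected edges: each point snaps to the
nearest edge pixel within a radius (default 5 px), distance ties broken by
row-major scan order for determinism; points with no edge in reach are dropped,
and fewer than 8 survivors is an error. Snapping is idempotent. Rasterization
of contours uses inside-or-on-boundary pixel-center containment (shapely), the
same rule the synthetic renderer uses, so the two agree pixel for pixel.

## Synthetic fluoroscopy generator

The generator emulates what matters to this pipeline: convex quadrilateral
bodies of distinct intensity (200) over a darker background (60), small
per-frame rigid motions applied about each body's current center (exactly the
tracker's motion model), optional Gaussian blur then additive Gaussian noise
(clipped, rounded), a single global seed with per-frame substreams (sequences
are byte-reproducible), and ground truth: true poses, true corners, and the
analytic translation/Cobb series computed from the true corners.

The canonical test scene (`flexion_scene`) uses 100×56 px bodies — vertebral
bodies at the scale of a high-resolution digital capture of a fluoroscopy
monitor — tilted 7° and placed off the pixel lattice (integer-aligned
axis-parallel rectangles are a rasterization degeneracy: their inclusive raster
is one row and column fatter than at any generic pose). Motion scripts are
on-grid bounded random walks, |Δθ| ≤ 2°, |Δx|, |Δy| ≤ 3 px per frame with
cumulative excursions capped at 8°/8 px — the slow-sweep regime of clinical
flexion–extension series.

What the generator does **not** emulate: bone texture and internal density
structure, overlapping anatomy (mandible, shoulders), radiographic
magnification or perspective, exposure drift, and deformable endplates. Passing
tests therefore establish the correctness of the algorithmic chain — search
optimality, geometric exactness, noise robustness of the binary-overlap score
at realistic contrast — not clinical accuracy on real fluoroscopy, which
additionally depends on segmentation quality in the presence of those factors.

## Outputs

The text report is TSV with a commented header (tool version, configuration
hash, column schema), one row per vertebra per frame (pose deltas vs the
previous frame) and one row per adjacent pair per frame (translation, relative
rotation, Cobb), numerics at 4 decimals, rows ordered by (frame, id). Data
lines are a pure function of inputs and configuration; there is no timestamp
unless explicitly requested, and reruns are byte-identical. Overlays render
each binary frame with every vertebra's transformed template footprint and
propagated corner quad tinted in a fixed per-vertebra palette color, blended at
configurable opacity — the visual check users rely on to trust the numbers.

## Degenerate inputs and numerical tolerances

Collinear corners, coincident edge midpoints and coincident pair centers raise
geometry errors; `signed_position_along` rejects points more than 1e-6 px off
the line. Line directions are unit to 1e-9. The perpendicular-bisector flip
test uses a −1e-12 tolerance so exactly perpendicular midlines keep their given
orientation. Angle computations use `atan2` (exact at the 1e-9° level the
tests demand). Templates need ≥ 16 one-pixels; frames loaded from disk must be
at least 32 px on a side (in-memory arrays of any size are accepted so small
worked examples remain expressible).

## Problem sizes used in validation

The test suite and the acceptance script use 10-frame, 2-vertebra sequences at
~280×340 px (noise-free exactness, noisy recovery over 20 seeds at σ = 10,
blur 1), 200 randomized 48×48 instances for brute-force equivalence, and
hundreds of randomized quad pairs for the closed-form geometry — sizes chosen
to exercise every code path while keeping the full suite under a minute.
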