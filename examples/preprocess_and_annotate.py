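"""The preprocessing chain and the edge-constrained annotation rule.

Renders one synthetic frame, applies contrast normalization, histogram
equalization, Canny edge detection and Otsu binarization, then snaps a
deliberately shaky hand-drawn contour onto the detected edges — the software's
replacement for a steady expert hand. Prints the pixel statistics at each
stage and how far the contour points moved.
"""

import numpy as np

from vertetrack.annotation import ContourPolyline, snap_contour_to_edges
from vertetrack.geometry import Point2D
from vertetrack.imaging import (
    binarize,
    canny_edges,
    equalize_histogram,
    normalize_contrast,
    otsu_threshold,
)
from vertetrack.synthetic import flexion_scene, render_frame

spec = flexion_scene(1, n_vertebrae=2, seed=3, noise_sigma=8.0, blur_sigma=1.0)
frame = render_frame(spec, 0)
print(f"raw frame      : {frame.width}x{frame.height}, "
      f"intensity range [{frame.pixels.min()}, {frame.pixels.max()}]")

norm = normalize_contrast(frame)
print(f"normalized     : range [{norm.pixels.min()}, {norm.pixels.max()}] (full 8-bit stretch)")

eq = equalize_histogram(norm)
edges = canny_edges(eq, 50, 150)
print(f"canny edges    : {int(edges.pixels.sum())} edge pixels")

thr = otsu_threshold(norm)
region = binarize(norm, thr)
print(f"otsu threshold : {thr:.0f} -> region map with {int(region.pixels.sum())} foreground px "
      f"({100 * region.pixels.mean():.1f}% of the frame)")

# a shaky contour near the upper body's true boundary
rng = np.random.default_rng(5)
quad = spec.vertebrae[0].quad
pts = []
for a, b in zip(quad.boundary(), quad.boundary()[1:] + quad.boundary()[:1]):
    for t in np.linspace(0, 1, 6, endpoint=False):
        x = a.x + t * (b.x - a.x) + rng.normal(0, 1.2)
        y = a.y + t * (b.y - a.y) + rng.normal(0, 1.2)
        pts.append(Point2D(x, y))
shaky = ContourPolyline(tuple(pts), closed=True, vertebra_id=quad.vertebra_id)

snapped = snap_contour_to_edges(shaky, edges, radius=5)
moves = [np.hypot(p.x - q.x, p.y - q.y) for p, q in zip(shaky.points, snapped.points)]
print(f"snapped contour: {len(snapped.points)}/{len(shaky.points)} points kept, "
      f"mean snap distance {np.mean(moves):.2f} px (every point now on an edge pixel)")
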