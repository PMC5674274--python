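"""Frame-to-frame vertebra tracking by exhaustive rigid-pose coincidence search.

Each vertebra is represented by a rigid binary template captured from the
expert-annotated first frame. For every subsequent frame the tracker evaluates
the *coincidence* — the fraction of template 1-pixels that land on 1-pixels of
the frame's binary map — over an exhaustive grid of candidate pose deltas
(rotation, vertical shift, horizontal shift) applied to the previous frame's
answer, and keeps the grid point with the highest coincidence. This is
case-based reasoning in the plainest sense: each frame's solved pose seeds the
next frame's search.

The search is vectorized but extensionally identical to the naive triple loop
(theta outer, then dy, then dx, each from negative to positive), including the
tie-break: ties on score go to the smaller |dtheta|, then |dy|, then |dx|,
then the first-encountered grid point. The least-motion preference encodes the
prior that consecutive fluoroscopic frames differ little.

Sampling is nearest-neighbour with the half-up rounding ``floor(v + 0.5)``,
which commutes with integer shifts; every score is therefore an exact rational
``hits / template_size``, and off-image samples count as misses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError, TrackingLostError
from .geometry import Point2D, VertebraQuad, geometric_center, rotate_points
from .imaging import BinaryMap

__all__ = [
    "VertebraTemplate",
    "PoseDelta",
    "SearchGrid",
    "FramePose",
    "TrackSequence",
    "build_template",
    "coincidence",
    "search_pose",
    "propagate_quad",
    "track_sequence",
    "DEFAULT_MIN_SCORE",
]

MIN_TEMPLATE_PIXELS = 16
DEFAULT_MIN_SCORE = 0.2


@dataclass(frozen=True)
class PoseDelta:
    """Rigid pose change relative to the previous frame.

    ``dtheta`` is in degrees, mathematically positive in image (x, y)
    coordinates; ``dx`` and ``dy`` are horizontal and vertical shifts in pixels.
    """

    dtheta: float = 0.0
    dx: float = 0.0
    dy: float = 0.0

    def is_identity(self) -> bool:
        return self.dtheta == 0.0 and self.dx == 0.0 and self.dy == 0.0


@dataclass(frozen=True)
class SearchGrid:
    """Symmetric exhaustive search grid: dtheta in ±theta_max stepped by
    theta_step, dx and dy in ±shift_max stepped by shift_step.

    The 1° default rotation resolution matches the discrimination limit of
    binary-overlap matching for body-scale templates: a finer step changes the
    nearest-neighbour rasterization of a vertebral body by fewer pixels than
    boundary rounding fluctuates, so sub-degree candidates are not reliably
    distinguishable and only slow the search down.
    """

    theta_max: float = 10.0
    theta_step: float = 1.0
    shift_max: float = 15.0
    shift_step: float = 1.0

    def __post_init__(self) -> None:
        if min(self.theta_max, self.theta_step, self.shift_max, self.shift_step) <= 0:
            raise ParameterError("all grid bounds and steps must be positive")
        if self.theta_step > self.theta_max or self.shift_step > self.shift_max:
            raise ParameterError("grid step cannot exceed its bound")

    def theta_values(self) -> np.ndarray:
        n = int(math.floor(self.theta_max / self.theta_step + 1e-9))
        return np.arange(-n, n + 1) * self.theta_step

    def shift_values(self) -> np.ndarray:
        n = int(math.floor(self.shift_max / self.shift_step + 1e-9))
        return np.arange(-n, n + 1) * self.shift_step


@dataclass(frozen=True)
class VertebraTemplate:
    """The binary vertebra-section image captured from frame 0, plus the
    reference corner quad and the rotation pivot."""

    mask: np.ndarray  # uint8 {0,1}, restricted to a bounding box
    bbox_origin: tuple[int, int]  # (x0, y0) of mask[0, 0] in image coordinates
    reference_quad: VertebraQuad
    reference_center: Point2D
    vertebra_id: str = ""

    def __post_init__(self) -> None:
        if self.mask.ndim != 2 or self.mask.dtype != np.uint8:
            raise ParameterError("template mask must be a 2-D uint8 {0,1} array")
        n = int(self.mask.sum())
        if n < MIN_TEMPLATE_PIXELS:
            raise ParameterError(
                f"template {self.vertebra_id!r} has {n} one-pixels; "
                f"need at least {MIN_TEMPLATE_PIXELS}"
            )
        x0, y0 = self.bbox_origin
        h, w = self.mask.shape
        c = self.reference_center
        if not (x0 - 0.5 <= c.x <= x0 + w - 0.5 and y0 - 0.5 <= c.y <= y0 + h - 0.5):
            raise ParameterError("reference_center lies outside the template bounding box")

    def points(self) -> np.ndarray:
        """Centers of the template 1-pixels as an (N, 2) float (x, y) array."""
        rc = np.argwhere(self.mask == 1)
        x0, y0 = self.bbox_origin
        return np.stack([rc[:, 1] + float(x0), rc[:, 0] + float(y0)], axis=1)


def build_template(substrate: BinaryMap, region: BinaryMap, quad: VertebraQuad) -> VertebraTemplate:
    """Capture a template from frame 0.

    ``substrate`` is the frame-0 binary map tracking will run on (region or edge
    map); ``region`` is the rasterized expert contour (or corner quad) selecting
    which of its pixels belong to this vertebra.
    """
    if substrate.pixels.shape != region.pixels.shape:
        raise ParameterError("substrate and region masks must share a shape")
    mask = (substrate.pixels & region.pixels).astype(np.uint8)
    ys, xs = np.nonzero(mask)
    if xs.size < MIN_TEMPLATE_PIXELS:
        raise ParameterError(
            f"template {quad.vertebra_id!r}: only {xs.size} substrate pixels inside "
            "the annotated region"
        )
    x0, x1 = int(xs.min()), int(xs.max())
    y0, y1 = int(ys.min()), int(ys.max())
    return VertebraTemplate(
        mask=mask[y0 : y1 + 1, x0 : x1 + 1],
        bbox_origin=(x0, y0),
        reference_quad=quad,
        reference_center=geometric_center(quad),
        vertebra_id=quad.vertebra_id,
    )


def _round_half_up(v: np.ndarray) -> np.ndarray:
    # floor(v + 0.5): commutes with integer shifts, unlike banker's rounding
    return np.floor(v + 0.5).astype(np.int64)


def _sample_hits(image: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Sum of image values at integer (x, y) positions; out-of-image = 0."""
    h, w = image.shape
    valid = (x >= 0) & (x < w) & (y >= 0) & (y < h)
    vals = np.zeros(x.shape, dtype=np.int64)
    vals[valid] = image[y[valid], x[valid]]
    return vals


def _coincidence_points(
    points: np.ndarray, pivot, image: np.ndarray, pose: PoseDelta
) -> tuple[int, int]:
    """(hits, n) for a point cloud under one pose: rotate about pivot, shift,
    nearest-neighbour sample."""
    rp = rotate_points(points, pose.dtheta, pivot)
    xi = _round_half_up(rp[:, 0] + pose.dx)
    yi = _round_half_up(rp[:, 1] + pose.dy)
    return int(_sample_hits(image, xi, yi).sum()), points.shape[0]


def coincidence(template: VertebraTemplate, next_image: BinaryMap, pose: PoseDelta) -> float:
    """Fraction of template 1-pixels landing on 1-pixels of ``next_image`` when
    the template is rotated by ``pose.dtheta`` about its reference center and
    shifted by ``(pose.dx, pose.dy)``."""
    pts = template.points()
    hits, n = _coincidence_points(pts, template.reference_center, next_image.pixels, pose)
    return hits / n


def _hits_direct(rp: np.ndarray, image: np.ndarray, dyf: np.ndarray, dxf: np.ndarray) -> np.ndarray:
    """Hit counts for one rotated point cloud at every shift pair, by direct
    nearest-neighbour lookup (any real-valued shifts)."""
    xi = _round_half_up(rp[None, :, 0] + dxf[:, None])
    yi = _round_half_up(rp[None, :, 1] + dyf[:, None])
    return _sample_hits(image, xi, yi).sum(axis=1)


def _hits_correlate(rp: np.ndarray, image: np.ndarray, shifts: np.ndarray) -> np.ndarray:
    """Hit counts at every integer shift pair via cross-correlation.

    Because ``floor(v + 0.5) + d == floor(v + d + 0.5)`` for integer ``d``, the
    points can be rounded once; the hit count at shift (dy, dx) is then the
    cross-correlation of the rounded-point multiplicity array with the image.
    Counts are exact integers (the FFT result is rounded back; values are far
    below the float64 integer-precision limit).
    """
    from scipy.signal import fftconvolve

    xi = _round_half_up(rp[:, 0])
    yi = _round_half_up(rp[:, 1])
    x0, y0 = int(xi.min()), int(yi.min())
    w_arr = np.zeros((int(yi.max()) - y0 + 1, int(xi.max()) - x0 + 1))
    np.add.at(w_arr, (yi - y0, xi - x0), 1.0)

    s_int = shifts.astype(np.int64)
    lo, hi = int(s_int.min()), int(s_int.max())
    wh, ww = w_arr.shape
    h, w = image.shape
    # zero-padded image window covering the template box under every shift
    pad = np.zeros((wh + hi - lo, ww + hi - lo))
    ry0, rx0 = y0 + lo, x0 + lo  # image coords of pad[0, 0]
    sy0, sx0 = max(ry0, 0), max(rx0, 0)
    sy1, sx1 = min(ry0 + pad.shape[0], h), min(rx0 + pad.shape[1], w)
    if sy1 > sy0 and sx1 > sx0:
        pad[sy0 - ry0 : sy1 - ry0, sx0 - rx0 : sx1 - rx0] = image[sy0:sy1, sx0:sx1]
    corr = fftconvolve(pad, w_arr[::-1, ::-1], mode="valid")  # [dy - lo, dx - lo]
    iy = s_int - lo
    hits = corr[np.ix_(iy, iy)]  # rows = dy, cols = dx
    return np.floor(hits.ravel() + 0.5).astype(np.int64)  # dy outer, dx inner


def _search_points(
    points: np.ndarray, pivot, image: np.ndarray, grid: SearchGrid
) -> tuple[PoseDelta, int, int]:
    """Exhaustive search over the grid for a point-cloud template.

    Returns (best PoseDelta, hits, n). Extensionally equal to evaluating
    ``_coincidence_points`` at every grid triple in loop order theta, dy, dx
    and keeping the maximum with the least-motion tie-break; integral shift
    grids go through the exact correlation fast path.
    """
    thetas = grid.theta_values()
    shifts = grid.shift_values()
    dyv, dxv = np.meshgrid(shifts, shifts, indexing="ij")  # dy outer, dx inner
    dyf = dyv.ravel()
    dxf = dxv.ravel()
    n = points.shape[0]
    if n == 0:
        raise ParameterError("empty template")
    integral = bool(np.all(shifts == np.floor(shifts)))

    best_hits = -1
    best_key: tuple = ()
    best_pose = PoseDelta()
    for it, th in enumerate(thetas):
        rp = rotate_points(points, float(th), pivot)
        if integral:
            hits = _hits_correlate(rp, image, shifts)
        else:
            hits = _hits_direct(rp, image, dyf, dxf)
        hmax = int(hits.max())
        if hmax < best_hits:
            continue
        for js in np.nonzero(hits == hmax)[0]:
            key = (-hmax, abs(float(th)), abs(float(dyf[js])), abs(float(dxf[js])), it, int(js))
            if best_hits < hmax or key < best_key:
                best_hits = hmax
                best_key = key
                best_pose = PoseDelta(float(th), float(dxf[js]), float(dyf[js]))
    return best_pose, best_hits, n


def search_pose(
    template: VertebraTemplate,
    next_image: BinaryMap,
    grid: SearchGrid,
    *,
    min_score: float = DEFAULT_MIN_SCORE,
    frame_index: int | None = None,
) -> tuple[PoseDelta, float]:
    """Best pose delta on the grid by exhaustive coincidence maximization.

    Raises :class:`TrackingLostError` when even the best grid point scores
    below ``min_score`` — a loud failure beats silently tracking background.
    """
    pose, hits, n = _search_points(
        template.points(), template.reference_center, next_image.pixels, grid
    )
    score = hits / n
    if score < min_score:
        raise TrackingLostError(template.vertebra_id, frame_index, score, min_score)
    return pose, score


def propagate_quad(quad: VertebraQuad, pose: PoseDelta, pivot: Point2D) -> VertebraQuad:
    """Apply a rigid pose delta to a corner quad: rotate about ``pivot`` by
    ``dtheta``, then shift by ``(dx, dy)``."""
    pts = rotate_points(quad.corner_array(), pose.dtheta, pivot)
    pts[:, 0] += pose.dx
    pts[:, 1] += pose.dy
    return VertebraQuad.from_array(pts, quad.vertebra_id)


@dataclass(frozen=True)
class FramePose:
    """One vertebra's state in one frame."""

    frame_index: int
    delta: PoseDelta  # vs the previous frame (identity at frame 0)
    cum_theta: float
    cum_dx: float
    cum_dy: float
    quad: VertebraQuad
    score: float


@dataclass
class TrackSequence:
    """Per-vertebra, per-frame track: pose deltas, cumulative pose sums,
    propagated corner quads and coincidence scores.

    ``failures`` maps a vertebra id to the :class:`TrackingLostError` that ended
    its track early; its ``poses`` list then stops at the last solved frame.
    """

    poses: dict[str, list[FramePose]] = field(default_factory=dict)
    failures: dict[str, TrackingLostError] = field(default_factory=dict)

    @property
    def vertebra_ids(self) -> list[str]:
        return list(self.poses.keys())

    def n_frames(self, vertebra_id: str) -> int:
        return len(self.poses[vertebra_id])

    def quad(self, vertebra_id: str, frame_index: int) -> VertebraQuad:
        return self.poses[vertebra_id][frame_index].quad


def track_sequence(
    frames: list[BinaryMap],
    templates: list[VertebraTemplate],
    grid: SearchGrid,
    *,
    min_score: float = DEFAULT_MIN_SCORE,
) -> TrackSequence:
    """Track every template through the frame sequence.

    Frame 0 is the expert answer: identity pose, score 1 by definition. Each
    later frame is solved by :func:`search_pose` seeded with the previous
    frame's answer; the rotation pivot is the geometric center of the current
    propagated quad. The template mask itself is rigid — only its pose
    accumulates. A lost vertebra is recorded in ``failures`` and the remaining
    vertebrae continue.
    """
    if len(frames) < 2:
        raise ParameterError("need at least two frames to track")
    out = TrackSequence()
    for tpl in templates:
        vid = tpl.vertebra_id
        points = tpl.points()
        quad = tpl.reference_quad
        track = [FramePose(0, PoseDelta(), 0.0, 0.0, 0.0, quad, 1.0)]
        cum_t = cum_x = cum_y = 0.0
        for k in range(1, len(frames)):
            pivot = geometric_center(quad)
            try:
                delta, hits, n = _search_points(points, pivot, frames[k].pixels, grid)
                score = hits / n
                if score < min_score:
                    raise TrackingLostError(vid, k, score, min_score)
            except TrackingLostError as e:
                out.failures[vid] = e
                break
            points = rotate_points(points, delta.dtheta, pivot)
            points[:, 0] += delta.dx
            points[:, 1] += delta.dy
            quad = propagate_quad(quad, delta, pivot)
            cum_t += delta.dtheta
            cum_x += delta.dx
            cum_y += delta.dy
            track.append(FramePose(k, delta, cum_t, cum_x, cum_y, quad, score))
        out.poses[vid] = track
    return out


def footprint_points(
    template: VertebraTemplate, track: list[FramePose], frame_index: int
) -> np.ndarray:
    """Template 1-pixel centers transformed to a given frame by replaying the
    recorded deltas (pivot = geometric center of each previous frame's quad)."""
    pts = template.points()
    for fp in track[1 : frame_index + 1]:
        pivot = geometric_center(track[fp.frame_index - 1].quad)
        pts = rotate_points(pts, fp.delta.dtheta, pivot)
        pts[:, 0] += fp.delta.dx
        pts[:, 1] += fp.delta.dy
    return pts
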