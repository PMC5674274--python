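"""Synthetic sagittal fluoroscopy phantoms with ground truth.

Emulates the essentials of a lateral cervical fluoroscopy sequence: convex
quadrilateral vertebral bodies of distinct intensity over a darker soft-tissue
background, undergoing small per-frame rigid motions in the plane, optionally
Gaussian-blurred and corrupted by additive Gaussian noise. Every generated
sequence carries its ground truth — true cumulative poses and corner quads per
frame, plus the analytic Frobin translation and Cobb angle series computed from
the true quads — so the tracker and the kinematics can be validated end to end
without any external data.

Script semantics match the tracker exactly: each per-frame
:class:`~vertetrack.tracking.PoseDelta` rotates the body about the geometric
center of its *current* quad, then shifts it. Rendering is pixel-center
rasterization (shared with :func:`~vertetrack.annotation.contour_to_mask`), so
a noise-free frame takes exactly two intensity values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from scipy import ndimage

from .annotation import contour_to_mask, quad_contour
from .errors import SceneSpecError
from .frobin import VertebraPair, cobb_angle, frobin_translation
from .geometry import VertebraQuad, geometric_center
from .imaging import ImageFrame
from .tracking import PoseDelta, propagate_quad

__all__ = [
    "VertebraMotion",
    "SceneSpec",
    "GroundTruth",
    "true_quads",
    "render_frame",
    "generate_sequence",
    "flexion_scene",
    "scene_from_json",
]


@dataclass(frozen=True)
class VertebraMotion:
    """One body in the scene: its frame-0 quad, its rendered intensity, and its
    per-frame motion script (length ``n_frames - 1``)."""

    quad: VertebraQuad
    intensity: int
    script: tuple[PoseDelta, ...]


@dataclass(frozen=True)
class SceneSpec:
    """Complete description of a synthetic sequence.

    ``margin`` is the clearance every corner must keep from the image border in
    every frame; the default leaves room for the tracker's default ±15 px shift
    search plus slack.
    """

    shape: tuple[int, int]  # (height, width)
    vertebrae: tuple[VertebraMotion, ...]
    n_frames: int
    background: int = 60
    noise_sigma: float = 0.0
    blur_sigma: float = 0.0
    seed: int = 0
    margin: float = 20.0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise SceneSpecError("n_frames must be >= 1")
        for v in self.vertebrae:
            if len(v.script) != self.n_frames - 1:
                raise SceneSpecError(
                    f"{v.quad.vertebra_id!r}: script length {len(v.script)} != "
                    f"n_frames - 1 = {self.n_frames - 1}"
                )
        ids = [v.quad.vertebra_id for v in self.vertebrae]
        if len(set(ids)) != len(ids):
            raise SceneSpecError(f"duplicate vertebra ids in scene: {ids}")


@dataclass
class GroundTruth:
    """True per-frame state of a generated sequence."""

    quads: dict[str, list[VertebraQuad]]  # per vertebra, one quad per frame
    cum_poses: dict[str, list[tuple[float, float, float]]]  # (theta, dx, dy) sums
    deltas: dict[str, list[PoseDelta]]  # per-frame deltas, identity at frame 0
    pairs: list[tuple[str, str]]  # adjacent (upper, lower) in scene order
    frobin_series: dict[str, list[float]] = field(default_factory=dict)
    cobb_series: dict[str, list[float]] = field(default_factory=dict)


def true_quads(spec: SceneSpec) -> dict[str, list[VertebraQuad]]:
    """Propagate every body's quad through its script; validates bounds.

    Raises :class:`SceneSpecError` naming the first frame at which any corner
    comes closer than ``spec.margin`` to the image border.
    """
    h, w = spec.shape
    out: dict[str, list[VertebraQuad]] = {}
    for v in spec.vertebrae:
        vid = v.quad.vertebra_id
        quads = [v.quad]
        for delta in v.script:
            quads.append(propagate_quad(quads[-1], delta, geometric_center(quads[-1])))
        for k, q in enumerate(quads):
            ca = q.corner_array()
            if (
                ca[:, 0].min() < spec.margin
                or ca[:, 0].max() > w - 1 - spec.margin
                or ca[:, 1].min() < spec.margin
                or ca[:, 1].max() > h - 1 - spec.margin
            ):
                raise SceneSpecError(
                    f"script drives vertebra {vid!r} within {spec.margin} px of the "
                    f"border at frame {k}"
                )
        out[vid] = quads
    return out


def _check_overlap(quads_at_frame: list[VertebraQuad], frame_index: int) -> None:
    polys = [shapely.Polygon([(p.x, p.y) for p in q.boundary()]) for q in quads_at_frame]
    for i in range(len(polys)):
        for j in range(i + 1, len(polys)):
            if polys[i].intersection(polys[j]).area > 1e-9:
                raise SceneSpecError(
                    f"vertebrae {quads_at_frame[i].vertebra_id!r} and "
                    f"{quads_at_frame[j].vertebra_id!r} overlap at frame {frame_index}"
                )


def _frame_rng(seed: int, frame_index: int) -> np.random.Generator:
    # per-frame substream of one global seed: byte-reproducible frames
    return np.random.default_rng([seed, frame_index])


def render_frame(
    spec: SceneSpec, frame_index: int, quads: dict[str, list[VertebraQuad]] | None = None
) -> ImageFrame:
    """Render one frame: flat background, bodies at their true-pose polygons,
    optional blur then additive Gaussian noise, clipped to [0, 255]."""
    if frame_index >= spec.n_frames:
        raise SceneSpecError(f"frame_index {frame_index} >= n_frames {spec.n_frames}")
    if quads is None:
        quads = true_quads(spec)
    at_frame = [quads[v.quad.vertebra_id][frame_index] for v in spec.vertebrae]
    _check_overlap(at_frame, frame_index)
    img = np.full(spec.shape, float(spec.background))
    for v, q in zip(spec.vertebrae, at_frame):
        mask = contour_to_mask(quad_contour(q), spec.shape).pixels.astype(bool)
        img[mask] = float(v.intensity)
    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma)
    if spec.noise_sigma > 0:
        img = img + _frame_rng(spec.seed, frame_index).normal(0.0, spec.noise_sigma, spec.shape)
    img = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    return ImageFrame(img, frame_index)


def _ground_truth(spec: SceneSpec, quads: dict[str, list[VertebraQuad]]) -> GroundTruth:
    cum: dict[str, list[tuple[float, float, float]]] = {}
    deltas: dict[str, list[PoseDelta]] = {}
    for v in spec.vertebrae:
        vid = v.quad.vertebra_id
        t = x = y = 0.0
        series = [(0.0, 0.0, 0.0)]
        for d in v.script:
            t, x, y = t + d.dtheta, x + d.dx, y + d.dy
            series.append((t, x, y))
        cum[vid] = series
        deltas[vid] = [PoseDelta()] + list(v.script)
    ids = [v.quad.vertebra_id for v in spec.vertebrae]
    pairs = list(zip(ids, ids[1:]))  # scene order: superior first
    gt = GroundTruth(quads=quads, cum_poses=cum, deltas=deltas, pairs=pairs)
    for up, lo in pairs:
        pid = f"{up}-{lo}"
        gt.frobin_series[pid] = [
            frobin_translation(VertebraPair(quads[up][k], quads[lo][k]))
            for k in range(spec.n_frames)
        ]
        gt.cobb_series[pid] = [
            cobb_angle(VertebraPair(quads[up][k], quads[lo][k]))
            for k in range(spec.n_frames)
        ]
    return gt


def generate_sequence(spec: SceneSpec, out_dir) -> GroundTruth:
    """Render the whole sequence to ``out_dir``.

    Writes ``frame_NNNN.png`` images, the frame-0 ``annotations.json`` (the true
    corner quads standing in for the expert input) and ``ground_truth.tsv``;
    returns the :class:`GroundTruth`.
    """
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    quads = true_quads(spec)
    for k in range(spec.n_frames):
        frame = render_frame(spec, k, quads)
        Image.fromarray(frame.pixels, mode="L").save(out / f"frame_{k:04d}.png")
    ann = {
        "vertebrae": [
            {
                "id": v.quad.vertebra_id,
                "corners": [[p.x, p.y] for p in v.quad.corners],
            }
            for v in spec.vertebrae
        ]
    }
    (out / "annotations.json").write_text(json.dumps(ann, indent=2) + "\n")
    gt = _ground_truth(spec, quads)
    lines = [
        "frame\tvertebra_id\tcum_theta\tcum_dx\tcum_dy\t"
        "c1x\tc1y\tc2x\tc2y\tc3x\tc3y\tc4x\tc4y"
    ]
    for k in range(spec.n_frames):
        for v in spec.vertebrae:
            vid = v.quad.vertebra_id
            t, x, y = gt.cum_poses[vid][k]
            cs = "\t".join(f"{c:.6f}" for p in quads[vid][k].corners for c in (p.x, p.y))
            lines.append(f"{k}\t{vid}\t{t:.6f}\t{x:.6f}\t{y:.6f}\t{cs}")
    (out / "ground_truth.tsv").write_text("\n".join(lines) + "\n")
    return gt


def _rect_quad(cx: float, cy: float, half_w: float, half_h: float, vid: str) -> VertebraQuad:
    """Axis-aligned rectangular body; anterior (+x) to the right."""
    return VertebraQuad.from_array(
        [
            [cx + half_w, cy - half_h],  # 1 anterior-superior
            [cx - half_w, cy - half_h],  # 2 posterior-superior
            [cx + half_w, cy + half_h],  # 3 anterior-inferior
            [cx - half_w, cy + half_h],  # 4 posterior-inferior
        ],
        vid,
    )


def _bounded_walk_scripts(
    rng: np.random.Generator,
    n_steps: int,
    theta_step: float,
    shift_step: float,
    max_step_theta: float,
    max_step_shift: float,
    cum_bound_theta: float,
    cum_bound_shift: float,
) -> list[PoseDelta]:
    """Random on-grid deltas forming a bounded walk (flexion-like back-and-forth).

    Every delta is an exact grid multiple; whenever a draw would push the
    cumulative sum past its bound the sign is flipped, so cumulative motion
    stays within ``cum_bound_*`` in every component.
    """
    kt = int(round(max_step_theta / theta_step))
    ks = int(round(max_step_shift / shift_step))
    cum = [0.0, 0.0, 0.0]
    bounds = [cum_bound_theta, cum_bound_shift, cum_bound_shift]
    steps = [theta_step, shift_step, shift_step]
    ks_all = [kt, ks, ks]
    out = []
    for _ in range(n_steps):
        d = []
        for i in range(3):
            v = float(rng.integers(-ks_all[i], ks_all[i] + 1)) * steps[i]
            if abs(cum[i] + v) > bounds[i]:
                v = -v
            cum[i] += v
            d.append(v)
        out.append(PoseDelta(d[0], d[1], d[2]))
    return out


def flexion_scene(
    n_frames: int = 10,
    *,
    n_vertebrae: int = 2,
    noise_sigma: float = 0.0,
    blur_sigma: float = 0.0,
    seed: int = 0,
    theta_step: float = 1.0,
    shift_step: float = 1.0,
    shape: tuple[int, int] | None = None,
) -> SceneSpec:
    """A canonical flexion-extension-like scene used throughout the tests.

    Bodies are 100 x 56 px rectangles — the scale of a vertebral body in a
    high-resolution digital capture of a fluoroscopy sequence — at intensity
    200 over background 60 (the strong bone/soft-tissue contrast left after
    contrast normalization), tilted 7 degrees and placed off the pixel lattice,
    as real anatomy always is. Per-frame motion is an on-grid bounded random
    walk: |dtheta| <= 2 deg and |dx|, |dy| <= 3 px per frame with cumulative
    excursions capped at 8 deg / 8 px, the small inter-frame motion regime of a
    slow flexion-extension sweep.
    """
    rng = np.random.default_rng([seed, 777])
    ids = ["C2", "C3", "C4", "C5", "C6", "C7"][:n_vertebrae]
    half_w, half_h = 50.0, 28.0
    spacing = 2 * half_h + 34.0
    if shape is None:
        side = int(2 * half_w + 180)
        shape = (max(side, int(spacing * n_vertebrae + 160)), side)
    h, w = shape
    top = h / 2.0 - spacing * (n_vertebrae - 1) / 2.0
    bodies = []
    for i, vid in enumerate(ids):
        quad = _rect_quad(w / 2.0 + 0.37, top + i * spacing + 0.21, half_w, half_h, vid)
        quad = propagate_quad(quad, PoseDelta(7.0, 0.0, 0.0), geometric_center(quad))
        script = _bounded_walk_scripts(
            rng,
            n_frames - 1,
            theta_step=theta_step,
            shift_step=shift_step,
            max_step_theta=2.0,
            max_step_shift=3.0,
            cum_bound_theta=8.0,
            cum_bound_shift=8.0,
        )
        bodies.append(VertebraMotion(quad, 200, tuple(script)))
    return SceneSpec(
        shape=shape,
        vertebrae=tuple(bodies),
        n_frames=n_frames,
        background=60,
        noise_sigma=noise_sigma,
        blur_sigma=blur_sigma,
        seed=seed,
    )


def scene_from_json(path) -> SceneSpec:
    """Load a scene spec from JSON (the ``vertetrack simulate`` input format)."""
    doc = json.loads(Path(path).read_text())
    bodies = []
    for rec in doc["vertebrae"]:
        quad = VertebraQuad.from_array(rec["corners"], rec["id"])
        script = tuple(PoseDelta(float(t), float(x), float(y)) for t, x, y in rec.get("script", []))
        bodies.append(VertebraMotion(quad, int(rec.get("intensity", 200)), script))
    return SceneSpec(
        shape=tuple(doc["shape"]),
        vertebrae=tuple(bodies),
        n_frames=int(doc["n_frames"]),
        background=int(doc.get("background", 60)),
        noise_sigma=float(doc.get("noise_sigma", 0.0)),
        blur_sigma=float(doc.get("blur_sigma", 0.0)),
        seed=int(doc.get("seed", 0)),
        margin=float(doc.get("margin", 20.0)),
    )
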