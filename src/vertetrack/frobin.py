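"""Frobin intervertebral kinematics from corner quads.

Given the four corner points of two adjacent vertebral bodies, three measures
are computed per frame:

* **translation** — the midlines of both bodies are drawn, the bisector of the
  angle between them is constructed, and a perpendicular is dropped from each
  body's geometric center onto the bisector. The translation is the signed
  distance between the two perpendicular feet along the bisector; positive when
  the upper body's foot is ahead of (anterior to) the lower body's foot,
  negative when it is behind. Measuring along the bisector rather than either
  midline is what makes the protocol robust to small positioning differences.
* **relative rotation** — the acute angle between the two midlines.
* **Cobb angle** — the angle between the perpendiculars erected on the two
  midlines. For lines in a plane this equals the angle between the midlines
  themselves; both constructions are kept as independent code paths and
  cross-checked in the tests.

Units are pixels and degrees throughout. No millimetre calibration is implied;
an optional ``mm_per_pixel`` scale can be applied to translations when known.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, GeometryError
from .geometry import (
    Line2D,
    VertebraQuad,
    angle_between,
    bisector,
    foot_of_perpendicular,
    geometric_center,
    midline,
    perpendicular,
    signed_position_along,
)
from .tracking import TrackSequence

__all__ = [
    "VertebraPair",
    "KinematicsRow",
    "frobin_translation",
    "relative_rotation",
    "cobb_angle",
    "kinematics_table",
]


@dataclass(frozen=True)
class VertebraPair:
    """Two anatomically adjacent vertebral bodies; ``upper`` is the superior one."""

    upper: VertebraQuad
    lower: VertebraQuad

    def __post_init__(self) -> None:
        cu, cl = geometric_center(self.upper), geometric_center(self.lower)
        if cu.x == cl.x and cu.y == cl.y:
            raise GeometryError("upper and lower vertebrae have coincident centers")

    @property
    def pair_id(self) -> str:
        return f"{self.upper.vertebra_id}-{self.lower.vertebra_id}"


def _anterior_bisector(pair: VertebraPair) -> tuple[Line2D, Line2D, Line2D]:
    """Midlines of both bodies plus their bisector oriented anteriorly.

    Midline directions point posterior → anterior by construction; the bisector
    direction is flipped, if needed, so its dot product with the mean midline
    direction is positive, which defines "ahead" on the bisector.
    """
    mu = midline(pair.upper)
    ml = midline(pair.lower)
    if float(mu.d() @ ml.d()) < -1e-12:
        raise GeometryError(
            f"midlines of pair {pair.pair_id!r} point in opposing anterior "
            "directions; the corner labelling of the two quads is inconsistent"
        )
    b = bisector(mu, ml)
    mean_dir = mu.d() + ml.d()
    bd = b.d()
    if float(bd @ mean_dir) < 0:
        b = Line2D(b.point, (-bd[0], -bd[1]))
    return mu, ml, b


def frobin_translation(pair: VertebraPair, *, mm_per_pixel: float | None = None) -> float:
    """Signed intervertebral translation of the upper body relative to the lower.

    Positive = the upper body's center projects anterior to the lower body's
    center on the midline bisector (forward/anterior slip); negative =
    posterior. In pixels, or millimetres when ``mm_per_pixel`` is given.
    """
    _, _, b = _anterior_bisector(pair)
    fu = foot_of_perpendicular(geometric_center(pair.upper), b)
    fl = foot_of_perpendicular(geometric_center(pair.lower), b)
    t = signed_position_along(fu, b) - signed_position_along(fl, b)
    return t * mm_per_pixel if mm_per_pixel else t


def relative_rotation(pair: VertebraPair) -> float:
    """Acute angle in degrees, in [0, 90], between the two body midlines."""
    return angle_between(midline(pair.upper), midline(pair.lower))


def cobb_angle(pair: VertebraPair, *, signed: bool = False) -> float:
    """Cobb angle of the pair: erect the perpendicular on each body midline and
    return the angle the two perpendiculars form, in [0, 90].

    With ``signed=True`` the magnitude is given the sign of the rotation from
    the lower to the upper midline (positive = mathematically positive in image
    coordinates).
    """
    mu = midline(pair.upper)
    ml = midline(pair.lower)
    pu = perpendicular(mu, geometric_center(pair.upper))
    pl = perpendicular(ml, geometric_center(pair.lower))
    ang = angle_between(pu, pl)
    if signed:
        du, dl = mu.d(), ml.d()
        if float(du @ dl) < 0:
            dl = -dl
        cross = float(dl[0] * du[1] - dl[1] * du[0])
        return float(np.copysign(ang, cross)) if cross else ang
    return ang


@dataclass(frozen=True)
class KinematicsRow:
    """One output record: either a single-vertebra motion row (pose delta vs the
    previous frame) or an adjacent-pair row (Frobin measures on that frame)."""

    frame_index: int
    subject_id: str  # vertebra id or "upper-lower" pair id
    kind: str  # "single" | "pair"
    dtheta_prev: float | None = None
    dx_prev: float | None = None
    dy_prev: float | None = None
    frobin_translation: float | None = None
    relative_rotation: float | None = None
    cobb_angle: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("single", "pair"):
            raise ConfigurationError(f"unknown row kind {self.kind!r}")
        single = (self.dtheta_prev, self.dx_prev, self.dy_prev)
        pairf = (self.frobin_translation, self.relative_rotation, self.cobb_angle)
        if self.kind == "single" and (any(v is None for v in single) or any(v is not None for v in pairf)):
            raise ConfigurationError("single rows carry pose deltas only")
        if self.kind == "pair" and (any(v is None for v in pairf) or any(v is not None for v in single)):
            raise ConfigurationError("pair rows carry Frobin measures only")


def kinematics_table(
    tracks: TrackSequence,
    pairs: list[tuple[str, str]],
    *,
    mm_per_pixel: float | None = None,
) -> list[KinematicsRow]:
    """Flatten a track into output rows.

    Per frame: one single row per tracked vertebra (its pose delta relative to
    the previous frame; zeros at frame 0) and one pair row per configured
    adjacent pair (Frobin translation, relative rotation, Cobb angle computed on
    that frame's propagated quads). Pairs are ``(upper_id, lower_id)``. A pair
    row is emitted only for frames where both members are still tracked.
    """
    for up, lo in pairs:
        for vid in (up, lo):
            if vid not in tracks.poses:
                raise ConfigurationError(f"pair references unknown vertebra id {vid!r}")
    rows: list[KinematicsRow] = []
    n_frames = max((len(t) for t in tracks.poses.values()), default=0)
    for k in range(n_frames):
        for vid in tracks.vertebra_ids:
            track = tracks.poses[vid]
            if k >= len(track):
                continue
            fp = track[k]
            rows.append(
                KinematicsRow(
                    frame_index=k,
                    subject_id=vid,
                    kind="single",
                    dtheta_prev=fp.delta.dtheta,
                    dx_prev=fp.delta.dx,
                    dy_prev=fp.delta.dy,
                )
            )
        for up, lo in pairs:
            tu, tl = tracks.poses[up], tracks.poses[lo]
            if k >= len(tu) or k >= len(tl):
                continue
            pair = VertebraPair(tu[k].quad, tl[k].quad)
            rows.append(
                KinematicsRow(
                    frame_index=k,
                    subject_id=pair.pair_id,
                    kind="pair",
                    frobin_translation=frobin_translation(pair, mm_per_pixel=mm_per_pixel),
                    relative_rotation=relative_rotation(pair),
                    cobb_angle=cobb_angle(pair),
                )
            )
    rows.sort(key=lambda r: (r.frame_index, r.subject_id))
    return rows
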