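"""Exact planar landmark geometry for vertebral kinematics.

Coordinate convention: image coordinates, 0-based, pixel centers; ``x`` is the
column index and increases toward the anterior edge of the vertebral body (for
a left-facing sagittal view this is rightward), ``y`` is the row index and
increases downward. Rotations are given in degrees, mathematically positive in
``(x, y)``; with ``y`` pointing down a positive angle appears clockwise on
screen.

Corner convention for a vertebral body quadrilateral (all downstream geometry
depends on it):

* corner 1 — anterior-superior
* corner 2 — posterior-superior
* corner 3 — anterior-inferior
* corner 4 — posterior-inferior

so that the diagonals are (1, 4) and (2, 3), the anterior edge is (1, 3) and
the posterior edge is (2, 4). The body *midline* runs from the posterior edge
midpoint to the anterior edge midpoint, i.e. it points anteriorly; the
"forward = positive" sign of intervertebral translation follows from this
direction, so a quad facing either way in the image is handled by labelling
its corners anatomically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError

__all__ = [
    "Point2D",
    "Line2D",
    "VertebraQuad",
    "geometric_center",
    "midline",
    "angle_between",
    "bisector",
    "perpendicular",
    "foot_of_perpendicular",
    "signed_position_along",
    "rotate_point",
    "rotate_points",
]

_DEGENERATE = 1e-12


@dataclass(frozen=True)
class Point2D:
    """A point in image coordinates (x = column, y = row)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise GeometryError(f"non-finite point ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)

    @staticmethod
    def from_array(a) -> "Point2D":
        return Point2D(float(a[0]), float(a[1]))


def _midpoint(a: Point2D, b: Point2D) -> Point2D:
    return Point2D((a.x + b.x) / 2.0, (a.y + b.y) / 2.0)


@dataclass(frozen=True)
class Line2D:
    """An infinite oriented line: a point on it plus a unit direction."""

    point: Point2D
    direction: tuple[float, float]

    def __post_init__(self) -> None:
        n = math.hypot(*self.direction)
        if abs(n - 1.0) > 1e-9:
            raise GeometryError(f"line direction not unit length (norm {n})")

    @staticmethod
    def from_vector(point: Point2D, vec) -> "Line2D":
        vx, vy = float(vec[0]), float(vec[1])
        n = math.hypot(vx, vy)
        if n < _DEGENERATE:
            raise GeometryError("zero-length direction vector")
        return Line2D(point, (vx / n, vy / n))

    @staticmethod
    def through(p: Point2D, q: Point2D) -> "Line2D":
        return Line2D.from_vector(p, (q.x - p.x, q.y - p.y))

    def d(self) -> np.ndarray:
        return np.array(self.direction, dtype=float)


@dataclass(frozen=True)
class VertebraQuad:
    """Four expert corner points of one vertebral body (corner convention above).

    The corners must form a strictly convex quadrilateral whose boundary, in
    order, is 1 → 2 → 4 → 3, so that (1,4) and (2,3) are the diagonals and
    intersect at an interior point.
    """

    corners: tuple[Point2D, Point2D, Point2D, Point2D]
    vertebra_id: str = ""

    def __post_init__(self) -> None:
        if len(self.corners) != 4:
            raise GeometryError("a vertebra quad needs exactly four corners")
        c1, c2, c3, c4 = self.corners
        ring = [c1, c2, c4, c3]  # boundary order
        crosses = []
        for i in range(4):
            a, b, c = ring[i], ring[(i + 1) % 4], ring[(i + 2) % 4]
            cr = (b.x - a.x) * (c.y - b.y) - (b.y - a.y) * (c.x - b.x)
            crosses.append(cr)
        if any(abs(c) < _DEGENERATE for c in crosses) or not (
            all(c > 0 for c in crosses) or all(c < 0 for c in crosses)
        ):
            raise GeometryError(
                f"corners of {self.vertebra_id or 'quad'} do not form a strictly "
                "convex quadrilateral in the 1=ant-sup, 2=post-sup, 3=ant-inf, "
                "4=post-inf convention"
            )

    def corner_array(self) -> np.ndarray:
        """Corners as a (4, 2) float array in corner order 1..4."""
        return np.array([[c.x, c.y] for c in self.corners], dtype=float)

    def boundary(self) -> list[Point2D]:
        """Corners in boundary (polygon) order 1, 2, 4, 3."""
        c1, c2, c3, c4 = self.corners
        return [c1, c2, c4, c3]

    @staticmethod
    def from_array(a, vertebra_id: str = "") -> "VertebraQuad":
        pts = tuple(Point2D(float(x), float(y)) for x, y in np.asarray(a, dtype=float))
        return VertebraQuad(pts, vertebra_id)  # type: ignore[arg-type]


def _intersect(p1: Point2D, d1: np.ndarray, p2: Point2D, d2: np.ndarray) -> Point2D:
    """Intersection of two parametric lines; raises on parallel."""
    denom = d1[0] * d2[1] - d1[1] * d2[0]
    if abs(denom) < _DEGENERATE:
        raise GeometryError("lines are parallel; no unique intersection")
    rhs = np.array([p2.x - p1.x, p2.y - p1.y])
    t = (rhs[0] * d2[1] - rhs[1] * d2[0]) / denom
    return Point2D(p1.x + t * d1[0], p1.y + t * d1[1])


def geometric_center(quad: VertebraQuad) -> Point2D:
    """Geometric center of a vertebral body: intersection of diagonals (1,4) and (2,3)."""
    c1, c2, c3, c4 = quad.corners
    d1 = np.array([c4.x - c1.x, c4.y - c1.y])
    d2 = np.array([c3.x - c2.x, c3.y - c2.y])
    if np.hypot(*d1) < _DEGENERATE or np.hypot(*d2) < _DEGENERATE:
        raise GeometryError("degenerate diagonal (coincident corners)")
    return _intersect(c1, d1, c2, d2)


def midline(quad: VertebraQuad) -> Line2D:
    """Body midline: the line through the anterior-edge midpoint and the
    posterior-edge midpoint, oriented posterior → anterior."""
    c1, c2, c3, c4 = quad.corners
    m_ant = _midpoint(c1, c3)
    m_post = _midpoint(c2, c4)
    if math.hypot(m_ant.x - m_post.x, m_ant.y - m_post.y) < _DEGENERATE:
        raise GeometryError("anterior and posterior edge midpoints coincide")
    return Line2D.through(m_post, m_ant)


def angle_between(l1: Line2D, l2: Line2D) -> float:
    """Acute angle in degrees, in [0, 90], between two undirected lines."""
    d1, d2 = l1.d(), l2.d()
    dot = abs(float(d1 @ d2))
    cross = abs(float(d1[0] * d2[1] - d1[1] * d2[0]))
    return math.degrees(math.atan2(cross, dot))


def bisector(l1: Line2D, l2: Line2D) -> Line2D:
    """Bisector of the acute angle between two lines.

    The two directions are first aligned to within 90° (the second is flipped if
    it opposes the first), then the bisector passes through the intersection
    with direction ``d1 + d2``. Parallel lines have no intersection; the defined
    fallback is the parallel line midway between them.
    """
    d1, d2 = l1.d(), l2.d()
    if float(d1 @ d2) < -1e-12:  # tolerance: keep given orientations when perpendicular
        d2 = -d2
    cross = d1[0] * d2[1] - d1[1] * d2[0]
    if abs(cross) < 1e-12:
        # parallel: line midway between them, same direction
        foot = foot_of_perpendicular(l1.point, l2)
        mid = _midpoint(l1.point, foot)
        return Line2D.from_vector(mid, d1)
    p = _intersect(l1.point, d1, l2.point, d2)
    return Line2D.from_vector(p, d1 + d2)


def perpendicular(line: Line2D, through: Point2D) -> Line2D:
    """The line perpendicular to ``line`` passing through ``through``."""
    dx, dy = line.direction
    return Line2D(through, (-dy, dx))


def foot_of_perpendicular(p: Point2D, line: Line2D) -> Point2D:
    """Orthogonal projection of ``p`` onto ``line``."""
    a = line.point.as_array()
    d = line.d()
    q = a + float((p.as_array() - a) @ d) * d
    return Point2D.from_array(q)


def signed_position_along(q: Point2D, line: Line2D, *, tol: float = 1e-6) -> float:
    """Scalar coordinate of ``q`` along the line's direction from its reference point.

    ``q`` must lie on the line (within ``tol`` pixels of perpendicular distance);
    larger values are more anterior when the line direction points anteriorly.
    """
    a = line.point.as_array()
    d = line.d()
    r = q.as_array() - a
    t = float(r @ d)
    off = r - t * d
    if math.hypot(*off) > tol:
        raise GeometryError(f"point {q} is {math.hypot(*off):.3g} px off the line")
    return t


def rotate_points(pts: np.ndarray, theta_deg: float, pivot) -> np.ndarray:
    """Rotate an (N, 2) array of (x, y) points by ``theta_deg`` about ``pivot``."""
    th = math.radians(theta_deg)
    c, s = math.cos(th), math.sin(th)
    p = np.asarray(pts, dtype=float)
    if isinstance(pivot, Point2D):
        cx, cy = pivot.x, pivot.y
    else:
        cx, cy = float(pivot[0]), float(pivot[1])
    x = p[..., 0] - cx
    y = p[..., 1] - cy
    return np.stack([cx + c * x - s * y, cy + s * x + c * y], axis=-1)


def rotate_point(p: Point2D, theta_deg: float, pivot: Point2D) -> Point2D:
    return Point2D.from_array(rotate_points(p.as_array()[None, :], theta_deg, pivot)[0])
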