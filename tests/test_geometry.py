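import math

import numpy as np
import pytest

from vertetrack.errors import GeometryError
from vertetrack.geometry import (
    Line2D,
    Point2D,
    VertebraQuad,
    angle_between,
    bisector,
    foot_of_perpendicular,
    geometric_center,
    midline,
    perpendicular,
    rotate_point,
    rotate_points,
    signed_position_along,
)
from .conftest import random_quad, rect_quad


def quad(*pts, vid="V"):
    return VertebraQuad(tuple(Point2D(*p) for p in pts), vid)


class TestGeometricCenter:
    def test_unit_square(self):
        q = quad((0, 0), (1, 0), (0, 1), (1, 1))
        c = geometric_center(q)
        assert (c.x, c.y) == pytest.approx((0.5, 0.5), abs=1e-12)

    def test_parallelogram_center_is_diagonal_midpoint(self, rng):
        for _ in range(20):
            o = rng.uniform(-10, 10, 2)
            u = rng.uniform(1, 5, 2) * [1, -1]
            v = rng.uniform(1, 5, 2)
            # corners in the 1..4 convention: 1, 2 on top edge; 3, 4 below
            c1, c2 = o + u, o
            c3, c4 = o + u + v, o + v
            q = quad(c1, c2, c3, c4)
            c = geometric_center(q)
            mid = (c1 + c4) / 2
            assert (c.x, c.y) == pytest.approx(tuple(mid), abs=1e-9)

    def test_generic_quad_matches_independent_solver(self):
        q = quad((0, 0), (4, 1), (1, 3), (5, 5))
        c = geometric_center(q)
        # independent oracle: solve c1 + t(c4-c1) = c2 + s(c3-c2) as a 2x2 system
        d1, d2 = np.array([5.0, 5.0]), np.array([-3.0, 2.0])
        m = np.column_stack([d1, -d2])
        b = np.array([4.0, 1.0])  # c2 - c1
        t, _ = np.linalg.solve(m, b)
        expect = t * d1
        assert (c.x, c.y) == pytest.approx(tuple(expect), abs=1e-9)
        # and the point lies on both diagonals
        for p0, p1 in (((0, 0), (5, 5)), ((4, 1), (1, 3))):
            d = np.subtract(p1, p0)
            r = np.array([c.x, c.y]) - p0
            assert abs(d[0] * r[1] - d[1] * r[0]) < 1e-9

    def test_center_strictly_inside_hull(self, rng):
        for _ in range(50):
            q = random_quad(rng)
            c = geometric_center(q)
            ring = q.boundary()
            for a, b in zip(ring, ring[1:] + ring[:1]):
                cross = (b.x - a.x) * (c.y - a.y) - (b.y - a.y) * (c.x - a.x)
                assert cross != 0
            signs = set()
            for a, b in zip(ring, ring[1:] + ring[:1]):
                cross = (b.x - a.x) * (c.y - a.y) - (b.y - a.y) * (c.x - a.x)
                signs.add(cross > 0)
            assert len(signs) == 1

    def test_collinear_corners_rejected(self):
        with pytest.raises(GeometryError):
            quad((0, 0), (1, 0), (2, 0), (3, 0))


class TestMidline:
    def test_axis_aligned_rectangle(self):
        q = rect_quad(2.0, 1.0, 2.0, 1.0)  # height 2, centered at y=1
        l = midline(q)
        assert l.point.y == pytest.approx(1.0)
        assert l.direction == pytest.approx((1.0, 0.0))  # anterior = +x

    def test_rigid_equivariance_under_rotation(self):
        q = rect_quad(0.0, 0.0, 4.0, 2.0)
        c = geometric_center(q)
        from vertetrack.tracking import PoseDelta, propagate_quad

        qr = propagate_quad(q, PoseDelta(10.0, 0, 0), c)
        l = midline(qr)
        th = math.radians(10.0)
        assert l.direction == pytest.approx((math.cos(th), math.sin(th)), abs=1e-12)

    def test_generic_quad_through_edge_midpoints(self, rng):
        for _ in range(20):
            q = random_quad(rng)
            c1, c2, c3, c4 = q.corners
            m_ant = ((c1.x + c3.x) / 2, (c1.y + c3.y) / 2)
            m_post = ((c2.x + c4.x) / 2, (c2.y + c4.y) / 2)
            l = midline(q)
            # both midpoints lie on the line
            for mx, my in (m_ant, m_post):
                r = np.array([mx - l.point.x, my - l.point.y])
                d = np.array(l.direction)
                assert abs(r[0] * d[1] - r[1] * d[0]) < 1e-9
            # direction points posterior -> anterior
            v = np.array([m_ant[0] - m_post[0], m_ant[1] - m_post[1]])
            assert float(v @ np.array(l.direction)) > 0


class TestAngles:
    def test_basic_angles(self):
        x = Line2D(Point2D(0, 0), (1.0, 0.0))
        assert angle_between(x, x) == 0.0
        y = Line2D(Point2D(0, 0), (0.0, 1.0))
        assert angle_between(x, y) == pytest.approx(90.0, abs=1e-12)
        d = Line2D(Point2D(0, 0), (1 / math.sqrt(2), 1 / math.sqrt(2)))
        assert angle_between(x, d) == pytest.approx(45.0, abs=1e-12)

    def test_angle_invariant_under_direction_flip(self, rng):
        for _ in range(20):
            v = rng.normal(size=2)
            w = rng.normal(size=2)
            l1 = Line2D.from_vector(Point2D(0, 0), v)
            l2 = Line2D.from_vector(Point2D(0, 0), w)
            l2f = Line2D.from_vector(Point2D(0, 0), -w)
            assert angle_between(l1, l2) == pytest.approx(angle_between(l1, l2f), abs=1e-9)
            assert 0.0 <= angle_between(l1, l2) <= 90.0


class TestBisector:
    def test_same_line(self):
        l = Line2D(Point2D(1, 2), (1.0, 0.0))
        b = bisector(l, l)
        assert abs(angle_between(b, l)) < 1e-9

    def test_symmetric_diagonals_give_horizontal(self):
        l1 = Line2D.from_vector(Point2D(0, 0), (1, 1))
        l2 = Line2D.from_vector(Point2D(0, 0), (1, -1))
        b = bisector(l1, l2)
        assert b.direction == pytest.approx((1.0, 0.0), abs=1e-12)
        assert (b.point.x, b.point.y) == pytest.approx((0.0, 0.0), abs=1e-12)

    def test_parallel_fallback_midway(self):
        l1 = Line2D(Point2D(0, 0), (1.0, 0.0))
        l2 = Line2D(Point2D(3, 4), (1.0, 0.0))
        b = bisector(l1, l2)
        assert b.point.y == pytest.approx(2.0)
        assert abs(b.direction[1]) < 1e-12

    def test_argument_order_irrelevant_as_undirected_line(self, rng):
        for _ in range(20):
            l1 = Line2D.from_vector(Point2D(*rng.normal(size=2)), rng.normal(size=2))
            l2 = Line2D.from_vector(Point2D(*rng.normal(size=2)), rng.normal(size=2))
            b12 = bisector(l1, l2)
            b21 = bisector(l2, l1)
            assert angle_between(b12, b21) == pytest.approx(0.0, abs=1e-7)
            # same line, not merely parallel: b21's point is on b12
            r = np.array([b21.point.x - b12.point.x, b21.point.y - b12.point.y])
            d = np.array(b12.direction)
            assert abs(r[0] * d[1] - r[1] * d[0]) < 1e-6

    def test_makes_equal_angles(self, rng):
        for _ in range(20):
            l1 = Line2D.from_vector(Point2D(0, 0), rng.normal(size=2))
            l2 = Line2D.from_vector(Point2D(0, 0), rng.normal(size=2))
            b = bisector(l1, l2)
            assert angle_between(b, l1) == pytest.approx(angle_between(b, l2), abs=1e-9)


class TestPerpendicularFootAndPosition:
    def test_point_on_line_is_its_own_foot(self):
        l = Line2D(Point2D(0, 0), (1.0, 0.0))
        f = foot_of_perpendicular(Point2D(3, 0), l)
        assert (f.x, f.y) == pytest.approx((3.0, 0.0), abs=1e-12)

    def test_drop_to_x_axis(self):
        l = Line2D(Point2D(0, 0), (1.0, 0.0))
        f = foot_of_perpendicular(Point2D(0, 5), l)
        assert (f.x, f.y) == pytest.approx((0.0, 0.0), abs=1e-12)

    def test_generic_against_projection_formula(self, rng):
        for _ in range(30):
            a = Point2D(*rng.normal(size=2))
            d = rng.normal(size=2)
            l = Line2D.from_vector(a, d)
            p = Point2D(*rng.normal(scale=10, size=2))
            f = foot_of_perpendicular(p, l)
            dn = np.array(l.direction)
            expect = np.array([a.x, a.y]) + float(
                (np.array([p.x, p.y]) - [a.x, a.y]) @ dn
            ) * dn
            assert (f.x, f.y) == pytest.approx(tuple(expect), abs=1e-9)
            # residual is orthogonal to the line
            assert abs(float((np.array([p.x, p.y]) - [f.x, f.y]) @ dn)) < 1e-9

    def test_signed_position(self):
        l = Line2D(Point2D(0, 0), (1.0, 0.0))
        assert signed_position_along(Point2D(0, 0), l) == 0.0
        assert signed_position_along(Point2D(3, 0), l) == pytest.approx(3.0)
        assert signed_position_along(Point2D(-2, 0), l) == pytest.approx(-2.0)

    def test_signed_position_rejects_off_line_point(self):
        l = Line2D(Point2D(0, 0), (1.0, 0.0))
        with pytest.raises(GeometryError):
            signed_position_along(Point2D(1, 0.01), l)

    def test_perpendicular_is_perpendicular(self):
        l = Line2D(Point2D(0, 0), (1.0, 0.0))
        p = perpendicular(l, Point2D(5, 5))
        assert angle_between(l, p) == pytest.approx(90.0, abs=1e-12)
        assert (p.point.x, p.point.y) == (5, 5)


class TestRigidEquivariance:
    def test_center_and_midline_transform_with_the_quad(self, rng):
        for _ in range(20):
            q = random_quad(rng)
            theta = rng.uniform(-180, 180)
            shift = rng.uniform(-50, 50, 2)
            pivot = Point2D(*rng.uniform(-20, 20, 2))

            pts = rotate_points(q.corner_array(), theta, pivot) + shift
            qt = VertebraQuad.from_array(pts, q.vertebra_id)

            c = geometric_center(q)
            ct = geometric_center(qt)
            c_expected = rotate_points(c.as_array()[None], theta, pivot)[0] + shift
            assert (ct.x, ct.y) == pytest.approx(tuple(c_expected), abs=1e-8)

            l, lt = midline(q), midline(qt)
            d_expected = rotate_points(np.array([l.direction]), theta, (0, 0))[0]
            assert np.allclose(lt.direction, d_expected, atol=1e-9)

    def test_rotate_point_periodicity(self):
        p = Point2D(3.0, 4.0)
        out = p
        for _ in range(4):
            out = rotate_point(out, 90.0, Point2D(1.0, 1.0))
        assert (out.x, out.y) == pytest.approx((3.0, 4.0), abs=1e-9)
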