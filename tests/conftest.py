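import numpy as np
import pytest

from vertetrack.geometry import Point2D, VertebraQuad
from vertetrack.tracking import PoseDelta, propagate_quad
from vertetrack.geometry import geometric_center


def rect_quad(cx, cy, half_w, half_h, vid="V"):
    """Axis-aligned rectangular body quad, anterior toward +x."""
    return VertebraQuad(
        (
            Point2D(cx + half_w, cy - half_h),  # 1 anterior-superior
            Point2D(cx - half_w, cy - half_h),  # 2 posterior-superior
            Point2D(cx + half_w, cy + half_h),  # 3 anterior-inferior
            Point2D(cx - half_w, cy + half_h),  # 4 posterior-inferior
        ),
        vid,
    )


def random_quad(rng, vid="V", center_span=40.0):
    """Random strictly convex quad in the corner convention: a randomly placed,
    rotated rectangle with corners jittered until convexity survives."""
    while True:
        cx, cy = rng.uniform(-center_span, center_span, 2)
        hw = rng.uniform(8, 30)
        hh = rng.uniform(5, 20)
        base = rect_quad(cx, cy, hw, hh, vid)
        theta = rng.uniform(-60, 60)
        q = propagate_quad(base, PoseDelta(theta, 0, 0), geometric_center(base))
        jitter = rng.uniform(-1.5, 1.5, (4, 2))
        pts = q.corner_array() + jitter
        try:
            return VertebraQuad.from_array(pts, vid)
        except Exception:
            continue


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def square_quad():
    return rect_quad(10.0, 10.0, 4.0, 3.0, "C3")
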