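import math

import numpy as np
import pytest

from vertetrack.annotation import contour_to_mask, quad_contour
from vertetrack.errors import ParameterError, TrackingLostError
from vertetrack.geometry import Point2D, geometric_center
from vertetrack.imaging import BinaryMap
from vertetrack.tracking import (
    PoseDelta,
    SearchGrid,
    VertebraTemplate,
    _coincidence_points,
    build_template,
    coincidence,
    propagate_quad,
    search_pose,
    track_sequence,
)
from .conftest import rect_quad


def block_template(y0=10, x0=10, h=6, w=6, vid="V"):
    """A solid h x w block template with its quad around it."""
    mask = np.ones((h, w), dtype=np.uint8)
    quad = rect_quad(x0 + (w - 1) / 2, y0 + (h - 1) / 2, w / 2, h / 2, vid)
    return VertebraTemplate(mask, (x0, y0), quad, geometric_center(quad), vid)


def render(template, shape, pose=PoseDelta()):
    """Binary map with 1s exactly at the template's (transformed, rounded) pixels."""
    from vertetrack.geometry import rotate_points

    pts = rotate_points(template.points(), pose.dtheta, template.reference_center)
    xi = np.floor(pts[:, 0] + pose.dx + 0.5).astype(int)
    yi = np.floor(pts[:, 1] + pose.dy + 0.5).astype(int)
    img = np.zeros(shape, dtype=np.uint8)
    img[yi, xi] = 1
    return BinaryMap(img)


class TestCoincidence:
    def test_perfect_overlap_scores_one(self):
        tpl = block_template()
        img = render(tpl, (30, 30))
        assert coincidence(tpl, img, PoseDelta()) == 1.0

    def test_empty_image_scores_zero(self):
        tpl = block_template()
        assert coincidence(tpl, BinaryMap(np.zeros((30, 30), np.uint8)), PoseDelta()) == 0.0

    def test_hand_counted_two_by_two_block(self):
        # 2x2 block of points at rows 0-1, cols 0-1; image ones at rows 0-1, cols 1-2
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])  # (x, y)
        img = np.zeros((3, 3), dtype=np.uint8)
        img[0:2, 1:3] = 1
        hits, n = _coincidence_points(pts, (0.5, 0.5), img, PoseDelta(0, 1, 0))
        assert (hits, n) == (4, 4)
        hits, n = _coincidence_points(pts, (0.5, 0.5), img, PoseDelta())
        assert (hits, n) == (2, 4)

    def test_off_image_samples_count_as_miss(self):
        tpl = block_template(x0=0, y0=0)
        img = render(tpl, (20, 20))
        s = coincidence(tpl, img, PoseDelta(0, -3, 0))
        assert s < 1.0

    def test_translation_invariance_of_template_and_image(self, rng):
        tpl = block_template()
        img = render(tpl, (40, 40))
        pose = PoseDelta(0, 2, -1)
        base = coincidence(tpl, img, pose)
        # shift both template and image by the same integer offset
        tpl2 = VertebraTemplate(
            tpl.mask, (tpl.bbox_origin[0] + 4, tpl.bbox_origin[1] + 3),
            propagate_quad(tpl.reference_quad, PoseDelta(0, 4, 3), tpl.reference_center),
            Point2D(tpl.reference_center.x + 4, tpl.reference_center.y + 3),
            tpl.vertebra_id,
        )
        img2 = np.zeros_like(img.pixels)
        img2[3:, 4:] = img.pixels[:-3, :-4]
        assert coincidence(tpl2, BinaryMap(img2), pose) == base

    def test_score_one_iff_every_pixel_hits(self):
        tpl = block_template()
        img = render(tpl, (30, 30))
        arr = img.pixels.copy()
        ys, xs = np.nonzero(arr)
        arr[ys[0], xs[0]] = 0  # remove one hit
        assert coincidence(tpl, BinaryMap(arr), PoseDelta()) == (tpl.mask.sum() - 1) / tpl.mask.sum()

    def test_template_minimum_size_enforced(self):
        with pytest.raises(ParameterError):
            VertebraTemplate(
                np.ones((2, 2), np.uint8), (0, 0), rect_quad(1, 1, 1, 1), Point2D(1, 1), "V"
            )


def brute_force_search(points, pivot, image, grid):
    """Naive triple-loop oracle with the spec tie-break, built on rotation math
    written out longhand (independent of the search implementation)."""
    best = None
    thetas = grid.theta_values()
    shifts = grid.shift_values()
    for th in thetas:
        rad = math.radians(float(th))
        c, s = math.cos(rad), math.sin(rad)
        for dy in shifts:
            for dx in shifts:
                hits = 0
                for x, y in points:
                    rx = pivot[0] + c * (x - pivot[0]) - s * (y - pivot[1])
                    ry = pivot[1] + s * (x - pivot[0]) + c * (y - pivot[1])
                    xi = math.floor(rx + dx + 0.5)
                    yi = math.floor(ry + dy + 0.5)
                    if 0 <= yi < image.shape[0] and 0 <= xi < image.shape[1]:
                        hits += int(image[yi, xi])
                key = (-hits, abs(float(th)), abs(float(dy)), abs(float(dx)))
                if best is None or key < best[0]:
                    best = (key, PoseDelta(float(th), float(dx), float(dy)), hits)
    return best[1], best[2]


class TestSearchPose:
    def test_identity_wins_on_identical_frame(self):
        tpl = block_template()
        img = render(tpl, (40, 40))
        pose, score = search_pose(tpl, img, SearchGrid(theta_max=4, theta_step=1, shift_max=4, shift_step=1))
        assert pose == PoseDelta(0.0, 0.0, 0.0)
        assert score == 1.0

    def test_pure_shift_recovered_exactly(self):
        tpl = block_template(y0=15, x0=15, h=8, w=10)
        img = render(tpl, (50, 50), PoseDelta(0, 3, -2))
        pose, score = search_pose(tpl, img, SearchGrid(theta_max=4, theta_step=1, shift_max=5, shift_step=1))
        assert pose == PoseDelta(0.0, 3.0, -2.0)
        assert score == 1.0

    @pytest.mark.parametrize("shift_step", [1.0, 0.5])
    def test_matches_brute_force_oracle(self, rng, shift_step):
        grid = SearchGrid(theta_max=3, theta_step=1.5, shift_max=2 * shift_step, shift_step=shift_step)
        for _ in range(15):
            mask = (rng.random((7, 8)) < 0.6).astype(np.uint8)
            while mask.sum() < 16:
                mask = (rng.random((7, 8)) < 0.7).astype(np.uint8)
            x0, y0 = int(rng.integers(5, 20)), int(rng.integers(5, 20))
            quad = rect_quad(x0 + 3.5, y0 + 3, 4, 3.5)
            tpl = VertebraTemplate(mask, (x0, y0), quad, geometric_center(quad), "V")
            img = (rng.random((32, 32)) < 0.4).astype(np.uint8)
            pose, score = search_pose(tpl, BinaryMap(img), grid, min_score=0.0)
            opose, ohits = brute_force_search(tpl.points(), (tpl.reference_center.x, tpl.reference_center.y), img, grid)
            assert pose == opose
            assert score == ohits / tpl.mask.sum()

    def test_lost_track_raises_with_context(self):
        tpl = block_template()
        empty = BinaryMap(np.zeros((40, 40), np.uint8))
        with pytest.raises(TrackingLostError) as e:
            search_pose(tpl, empty, SearchGrid(theta_max=2, theta_step=1, shift_max=2, shift_step=1), frame_index=7)
        assert e.value.vertebra_id == "V"
        assert e.value.frame_index == 7


class TestPropagateQuad:
    def test_identity(self, square_quad):
        out = propagate_quad(square_quad, PoseDelta(), Point2D(0, 0))
        assert np.allclose(out.corner_array(), square_quad.corner_array())

    def test_pure_shift(self, square_quad):
        out = propagate_quad(square_quad, PoseDelta(0, 5, 0), Point2D(0, 0))
        assert np.allclose(out.corner_array()[:, 0], square_quad.corner_array()[:, 0] + 5)
        assert np.allclose(out.corner_array()[:, 1], square_quad.corner_array()[:, 1])

    def test_four_quarter_turns_identity(self, square_quad):
        c = geometric_center(square_quad)
        out = square_quad
        for _ in range(4):
            out = propagate_quad(out, PoseDelta(90.0, 0, 0), c)
        assert np.allclose(out.corner_array(), square_quad.corner_array(), atol=1e-9)


class TestTrackSequence:
    def grid(self):
        return SearchGrid(theta_max=3, theta_step=1, shift_max=4, shift_step=1)

    def scene(self, deltas, shape=(64, 64)):
        quad = rect_quad(30, 30, 8, 5, "C3")
        region = contour_to_mask(quad_contour(quad), shape)
        tpl = build_template(region, region, quad)
        frames = [render(tpl, shape)]
        cur_pts = tpl.points()
        cur_quad = quad
        from vertetrack.geometry import rotate_points

        for d in deltas:
            pivot = geometric_center(cur_quad)
            cur_pts = rotate_points(cur_pts, d.dtheta, pivot)
            cur_pts[:, 0] += d.dx
            cur_pts[:, 1] += d.dy
            cur_quad = propagate_quad(cur_quad, d, pivot)
            img = np.zeros(shape, dtype=np.uint8)
            xi = np.floor(cur_pts[:, 0] + 0.5).astype(int)
            yi = np.floor(cur_pts[:, 1] + 0.5).astype(int)
            img[yi, xi] = 1
            frames.append(BinaryMap(img))
        return frames, [tpl]

    def test_static_sequence_gives_identity_poses(self):
        frames, tpls = self.scene([PoseDelta(), PoseDelta()])
        tr = track_sequence(frames, tpls, self.grid())
        for fp in tr.poses["C3"]:
            assert fp.delta == PoseDelta(0.0, 0.0, 0.0)
            assert fp.score == 1.0

    def test_scripted_integer_translations_recovered(self):
        script = [PoseDelta(0, 2, -1), PoseDelta(0, -3, 2), PoseDelta(0, 1, 1)]
        frames, tpls = self.scene(script)
        tr = track_sequence(frames, tpls, self.grid())
        got = [fp.delta for fp in tr.poses["C3"][1:]]
        assert got == script
        # cumulative sums accumulate the deltas
        assert tr.poses["C3"][-1].cum_dx == sum(d.dx for d in script)
        assert tr.poses["C3"][-1].cum_dy == sum(d.dy for d in script)

    def test_off_grid_half_step_within_one_step(self):
        script = [PoseDelta(0, 1.5, -0.5)]
        frames, tpls = self.scene(script)
        tr = track_sequence(frames, tpls, self.grid())
        d = tr.poses["C3"][1].delta
        assert abs(d.dx - 1.5) <= 1.0 and abs(d.dy + 0.5) <= 1.0

    def test_lost_vertebra_recorded_others_continue(self):
        frames, tpls = self.scene([PoseDelta(0, 1, 0)])
        # second vertebra whose body vanishes after frame 0
        quad2 = rect_quad(48, 48, 6, 4, "C4")
        region2 = contour_to_mask(quad_contour(quad2), (64, 64))
        tpl2 = build_template(region2, region2, quad2)
        frames0 = BinaryMap(frames[0].pixels | render(tpl2, (64, 64)).pixels)
        tr = track_sequence([frames0, frames[1]], tpls + [tpl2], self.grid())
        assert "C4" in tr.failures
        assert len(tr.poses["C4"]) == 1  # stopped after frame 0
        assert tr.poses["C3"][1].delta == PoseDelta(0.0, 1.0, 0.0)

    def test_needs_two_frames(self):
        frames, tpls = self.scene([])
        with pytest.raises(ParameterError):
            track_sequence(frames, tpls, self.grid())
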