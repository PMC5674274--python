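"""Frobin intervertebral measures on hand-built corner landmarks.

Builds two adjacent vertebral bodies from their four corner points, slips the
upper one 5 px anteriorly and tilts it 7 degrees, and prints the three pair
measures. The translation is the signed distance between the perpendicular
feet of the two body centers on the midline bisector (positive = upper body
anterior); relative rotation and Cobb angle both quantify the angle between
the body orientations and agree by construction.
"""

from vertetrack.frobin import VertebraPair, cobb_angle, frobin_translation, relative_rotation
from vertetrack.geometry import Point2D, VertebraQuad, geometric_center
from vertetrack.tracking import PoseDelta, propagate_quad


def body(cx, cy, half_w, half_h, vid):
    # corner order: 1 ant-sup, 2 post-sup, 3 ant-inf, 4 post-inf (anterior = +x)
    return VertebraQuad(
        (
            Point2D(cx + half_w, cy - half_h),
            Point2D(cx - half_w, cy - half_h),
            Point2D(cx + half_w, cy + half_h),
            Point2D(cx - half_w, cy + half_h),
        ),
        vid,
    )


lower = body(128, 180, 50, 28, "C4")

# pure anterior slip: the upper body translated 5 px forward, no tilt
slipped = VertebraPair(body(128 + 5, 100, 50, 28, "C3"), lower)
print(f"pair {slipped.pair_id}, pure 5 px anterior slip")
print(f"  frobin translation : {frobin_translation(slipped):+8.4f} px  (positive = anterior)")
print(f"  relative rotation  : {relative_rotation(slipped):8.4f} deg")

# pure tilt: the upper body rotated 7 deg about its own center
upper = body(128, 100, 50, 28, "C3")
tilted = VertebraPair(propagate_quad(upper, PoseDelta(7.0, 0, 0), geometric_center(upper)), lower)
print(f"\npair {tilted.pair_id}, pure 7 deg tilt of the upper body")
print(f"  frobin translation : {frobin_translation(tilted):+8.4f} px "
      "(tilting swings the bisector, so a small apparent slip remains)")
print(f"  relative rotation  : {relative_rotation(tilted):8.4f} deg")
print(f"  cobb angle         : {cobb_angle(tilted):8.4f} deg (perpendicular construction)")
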