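"""First-frame expert annotations: contours, corner quads, and the edge constraint.

The interactive drawing step is replaced by a declarative JSON file; the
edge-constraint behaviour the drawing tool enforced — the contour may not leave
the detected edges — is the :func:`snap_contour_to_edges` operation.

Annotation JSON schema (one record per vertebra)::

    {"vertebrae": [
        {"id": "C3",
         "corners": [[x, y], [x, y], [x, y], [x, y]],   # corner order 1..4
         "contour": [[x, y], ...]                        # optional, >= 8 points
        }, ...
    ]}

A bare top-level list of records is also accepted. Corners are authoritative
for all kinematic geometry; the contour is used only to build the tracking
template mask (the corner quad itself is rasterized when the contour is absent).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely

from .errors import AnnotationError, GeometryError, ParameterError, SchemaError
from .geometry import Point2D, VertebraQuad
from .imaging import BinaryMap

__all__ = [
    "ContourPolyline",
    "CornerAnnotation",
    "snap_contour_to_edges",
    "contour_to_mask",
    "load_annotations",
    "quad_contour",
]

MIN_CONTOUR_POINTS = 8


@dataclass(frozen=True)
class ContourPolyline:
    """An expert-drawn outer contour of one vertebral body."""

    points: tuple[Point2D, ...]
    closed: bool = True
    vertebra_id: str = ""

    def __post_init__(self) -> None:
        pts = self.points
        if len(pts) < 2:
            raise AnnotationError("contour needs at least two points")
        for a, b in zip(pts, pts[1:]):
            if a.x == b.x and a.y == b.y:
                raise AnnotationError("consecutive contour points must be distinct")

    def as_array(self) -> np.ndarray:
        return np.array([[p.x, p.y] for p in self.points], dtype=float)


@dataclass(frozen=True)
class CornerAnnotation:
    """The four expert corner points of one vertebra in the first frame."""

    quad: VertebraQuad
    frame_index: int = 0

    def __post_init__(self) -> None:
        if self.frame_index != 0:
            raise AnnotationError("corner annotations belong to frame 0")


def quad_contour(quad: VertebraQuad) -> ContourPolyline:
    """Closed contour tracing the quad boundary (corners in boundary order)."""
    return ContourPolyline(tuple(quad.boundary()), closed=True, vertebra_id=quad.vertebra_id)


def snap_contour_to_edges(raw: ContourPolyline, edges: BinaryMap, radius: float = 5.0) -> ContourPolyline:
    """Constrain a drawn contour onto detected edge pixels.

    Each input point moves to the nearest edge pixel within ``radius``; ties on
    distance are broken by row-major scan order so the result is deterministic.
    Points with no edge pixel within reach are dropped (the "hand vibration"
    the drawing tool would have refused to plot); consecutive duplicates
    created by snapping are collapsed. Fewer than 8 surviving points means the
    contour was drawn off the edges, which is an annotation error.
    """
    if radius < 1:
        raise ParameterError(f"snap radius must be >= 1, got {radius}")
    coords = np.argwhere(edges.pixels == 1)  # (row, col), row-major order
    if coords.size == 0:
        raise AnnotationError("edge map is empty; nothing to snap to")
    ex = coords[:, 1].astype(float)
    ey = coords[:, 0].astype(float)
    r2 = float(radius) * float(radius)
    snapped: list[Point2D] = []
    for p in raw.points:
        d2 = (ex - p.x) ** 2 + (ey - p.y) ** 2
        j = int(np.argmin(d2))  # first minimum in row-major order
        if d2[j] > r2:
            continue
        q = Point2D(float(ex[j]), float(ey[j]))
        if snapped and snapped[-1].x == q.x and snapped[-1].y == q.y:
            continue
        snapped.append(q)
    if raw.closed and len(snapped) > 1 and snapped[0] == snapped[-1]:
        snapped.pop()
    if len(snapped) < MIN_CONTOUR_POINTS:
        raise AnnotationError(
            f"contour {raw.vertebra_id!r} off edges: only {len(snapped)} points "
            f"within {radius} px of an edge pixel"
        )
    return ContourPolyline(tuple(snapped), raw.closed, raw.vertebra_id)


def _polygon(contour: ContourPolyline) -> shapely.Polygon:
    poly = shapely.Polygon([(p.x, p.y) for p in contour.points])
    if not poly.is_valid:
        raise AnnotationError(f"contour {contour.vertebra_id!r} is self-intersecting")
    if poly.area <= 0:
        raise AnnotationError(f"contour {contour.vertebra_id!r} has zero area")
    return poly


def contour_to_mask(contour: ContourPolyline, shape: tuple[int, int]) -> BinaryMap:
    """Rasterize a closed contour: 1-pixels are those whose centers lie inside
    or on the polygon boundary."""
    if not contour.closed:
        raise AnnotationError("only closed contours can be rasterized")
    poly = _polygon(contour)
    h, w = shape
    minx, miny, maxx, maxy = poly.bounds
    x0 = max(0, int(np.floor(minx)))
    x1 = min(w - 1, int(np.ceil(maxx)))
    y0 = max(0, int(np.floor(miny)))
    y1 = min(h - 1, int(np.ceil(maxy)))
    mask = np.zeros((h, w), dtype=np.uint8)
    if x1 >= x0 and y1 >= y0:
        xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
        inside = shapely.intersects_xy(poly, xs.ravel().astype(float), ys.ravel().astype(float))
        mask[y0 : y1 + 1, x0 : x1 + 1] = inside.reshape(xs.shape).astype(np.uint8)
    return BinaryMap(mask)


def _schema_error(i, rec_id, msg) -> SchemaError:
    return SchemaError(f"annotation record {i} (id={rec_id!r}): {msg}")


def load_annotations(path) -> list[tuple[CornerAnnotation, ContourPolyline | None]]:
    """Load and validate the first-frame annotation file.

    Returns one ``(CornerAnnotation, contour-or-None)`` pair per vertebra, in
    file order. Duplicate ids, malformed corner lists and non-convex quads are
    schema errors naming the offending record.
    """
    p = Path(path)
    if not p.exists():
        raise SchemaError(f"annotation file not found: {p}")
    try:
        doc = json.loads(p.read_text())
    except json.JSONDecodeError as e:
        raise SchemaError(f"{p}: invalid JSON: {e}") from e
    records = doc.get("vertebrae") if isinstance(doc, dict) else doc
    if not isinstance(records, list) or not records:
        raise SchemaError(f"{p}: expected a non-empty list of vertebra records")
    out: list[tuple[CornerAnnotation, ContourPolyline | None]] = []
    seen: set[str] = set()
    for i, rec in enumerate(records):
        if not isinstance(rec, dict):
            raise _schema_error(i, None, "record is not an object")
        vid = rec.get("id")
        if not isinstance(vid, str) or not vid:
            raise _schema_error(i, vid, "missing or empty 'id'")
        if vid in seen:
            raise _schema_error(i, vid, f"duplicate vertebra id {vid!r}")
        seen.add(vid)
        corners = rec.get("corners")
        if not (isinstance(corners, list) and len(corners) == 4):
            raise _schema_error(i, vid, "'corners' must be a list of four [x, y] pairs")
        try:
            pts = tuple(Point2D(float(c[0]), float(c[1])) for c in corners)
        except (TypeError, ValueError, IndexError) as e:
            raise _schema_error(i, vid, f"malformed corner coordinates: {e}") from e
        try:
            quad = VertebraQuad(pts, vid)  # type: ignore[arg-type]
        except GeometryError as e:
            raise _schema_error(i, vid, str(e)) from e
        contour = None
        if rec.get("contour") is not None:
            cpts = rec["contour"]
            if not (isinstance(cpts, list) and len(cpts) >= MIN_CONTOUR_POINTS):
                raise _schema_error(
                    i, vid, f"'contour' must list at least {MIN_CONTOUR_POINTS} points"
                )
            try:
                contour = ContourPolyline(
                    tuple(Point2D(float(c[0]), float(c[1])) for c in cpts),
                    closed=True,
                    vertebra_id=vid,
                )
            except (TypeError, ValueError, IndexError, AnnotationError) as e:
                raise _schema_error(i, vid, f"malformed contour: {e}") from e
        out.append((CornerAnnotation(quad, 0), contour))
    return out
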