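"""Exception hierarchy.

Every failure mode raised by the library derives from :class:`VertetrackError`
so callers (and the CLI) can catch one type.
"""


class VertetrackError(Exception):
    """Base class for all vertetrack errors."""


class ParameterError(VertetrackError, ValueError):
    """An operation was called with out-of-contract parameters."""


class GeometryError(VertetrackError):
    """Degenerate or inconsistent planar geometry (collinear corners, zero-length
    midline, point off a line it must lie on)."""


class AnnotationError(VertetrackError):
    """Invalid expert annotation: contour off the detected edges, degenerate or
    self-intersecting polygon."""


class SchemaError(AnnotationError):
    """Malformed annotation file; the message names the offending record/field."""


class TrackingLostError(VertetrackError):
    """Best coincidence fell below the lost-track floor.

    Carries the vertebra id and (when known) the frame index so that a pipeline
    can report which vertebra was lost and keep tracking the others.
    """

    def __init__(self, vertebra_id: str, frame_index: int | None, score: float, floor: float):
        self.vertebra_id = vertebra_id
        self.frame_index = frame_index
        self.score = score
        self.floor = floor
        where = f" at frame {frame_index}" if frame_index is not None else ""
        super().__init__(
            f"tracking lost for vertebra {vertebra_id!r}{where}: "
            f"best coincidence {score:.4f} < floor {floor:.4f}"
        )


class SceneSpecError(VertetrackError):
    """Invalid synthetic scene: overlapping bodies or a motion script that drives
    a vertebra out of the image."""


class ConfigurationError(VertetrackError):
    """Missing or inconsistent pipeline configuration/inputs."""
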