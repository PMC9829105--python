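"""Exception hierarchy.

Every domain error raised by this package derives from
:class:`CentroidTrackError`, so callers (and the CLI) can catch one type.
"""

from __future__ import annotations


class CentroidTrackError(Exception):
    """Base class for all errors raised by centroidtrack."""


class STLParseError(CentroidTrackError):
    """An STL file could not be parsed.

    Attributes
    ----------
    path : str
        File that failed.
    offset : int or None
        Byte offset at (or near) which the problem was detected.
    """

    def __init__(self, message: str, path: str = "", offset: int | None = None):
        super().__init__(message)
        self.path = path
        self.offset = offset


class MeshValidationError(CentroidTrackError):
    """A mesh violates the structural invariants (bad indices, degenerate
    faces, too few vertices/faces)."""

    def __init__(self, message: str, bad_faces: list[int] | None = None):
        super().__init__(message)
        self.bad_faces = bad_faces or []


class DegenerateMeshError(CentroidTrackError):
    """A geometric quantity is undefined for this mesh (e.g. total surface
    area below the degeneracy floor)."""


class FrameError(CentroidTrackError):
    """A Cartesian frame definition is malformed, skew or left-handed."""


class TrackingError(CentroidTrackError):
    """The tracking pipeline refused a case (comparability failure or
    alignment divergence).  Carries the offending reports."""

    def __init__(self, message: str, reports: list | None = None):
        super().__init__(message)
        self.reports = reports or []
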