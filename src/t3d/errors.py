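"""Exception hierarchy for the reconstruction pipeline.

Every stage raises a subclass of :class:`T3DError`, so the command-line
driver can abort with the failing stage's message and a nonzero exit code.
"""


class T3DError(Exception):
    """Base class for all pipeline errors."""


class FormatError(T3DError):
    """An input file is unreadable, empty, or violates its schema."""


class ParameterError(T3DError):
    """A numeric parameter is outside its valid range."""


class PreconditionError(T3DError):
    """An operation was called on data violating its contract."""


class RepairError(T3DError):
    """Mesh repair failed (e.g. a self-intersecting boundary loop)."""


class GeometryError(T3DError):
    """Degenerate geometry (e.g. collinear fiducials)."""


class OrientationError(T3DError):
    """Fiducial labels are inconsistent: the best rigid fit requires a reflection."""


class PlanError(T3DError):
    """A grossing plan is invalid for the given specimen."""


class FlippedSlideError(T3DError):
    """Registering a slide's ink marks requires a reflection (slide mounted mirror-wise)."""


class MisalignmentError(T3DError):
    """Ink-mark registration residual exceeds the configured tolerance."""


class TopologyError(T3DError):
    """Contour winding or correspondence cannot be made consistent."""


class GenerationError(T3DError):
    """Phantom generation parameters are inconsistent."""


class ExportError(T3DError):
    """Mesh export preconditions (watertightness, presence) are violated."""
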