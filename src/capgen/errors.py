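"""Exception hierarchy for the cap generation pipeline."""


class CapgenError(Exception):
    """Base class for all pipeline errors."""


class InvalidParameterError(CapgenError, ValueError):
    """A configuration or call parameter is out of its valid range."""


class GeometryError(CapgenError):
    """A geometric construction failed (plane misses mesh, point off surface, ...)."""


class TopologyError(CapgenError):
    """Mesh or polygon connectivity is not what the operation requires."""


class FormatError(CapgenError):
    """An input file does not match the expected container/schema."""


class ValidationError(CapgenError):
    """Input content is well-formed but violates a domain invariant."""


class InvalidFiducialError(ValidationError):
    """Fiducials are coincident, collinear, or otherwise unusable."""


class ConvergenceError(CapgenError):
    """An iterative solver exceeded its iteration budget.

    Carries the residual history so callers can diagnose the run.
    """

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals


class QualityError(CapgenError):
    """Output violates a quality contract (flipped triangles, self-intersections)."""


class PlacementError(CapgenError):
    """A feature (optode, holder, slit) cannot be placed where requested."""


class LibraryError(CapgenError):
    """A grommet library lookup failed."""


class SolidGeometryError(CapgenError):
    """Solid construction produced a non-manifold or otherwise invalid body."""
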