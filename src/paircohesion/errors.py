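"""Exception hierarchy for the paircohesion package."""


class PairCohesionError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(PairCohesionError, ValueError):
    """A parameter violates its documented domain (e.g. non-positive spacing)."""


class SingularFitError(PairCohesionError, ValueError):
    """A regression design is degenerate (e.g. all RSS values identical)."""


class MissingReceiverError(PairCohesionError, KeyError):
    """A detection references a receiver id absent from the array."""


class InsufficientDataError(PairCohesionError, ValueError):
    """Too few observations to compute the requested quantity."""


class DegenerateGeometryError(PairCohesionError, ValueError):
    """Geometry input is degenerate (collinear points, zero-area polygon)."""


class GridMismatchError(PairCohesionError, ValueError):
    """Two utilization distributions are not defined on the same grid."""


class SchemaError(PairCohesionError, ValueError):
    """An input table is missing a required column."""
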