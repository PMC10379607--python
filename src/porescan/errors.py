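"""Exception hierarchy for porescan.

All library errors derive from :class:`PoreScanError` so callers can catch
one base class; subclasses also derive from the closest builtin so idiomatic
``except ValueError`` style code keeps working.
"""


class PoreScanError(Exception):
    """Base class for all porescan errors."""


class InvalidArgumentError(PoreScanError, ValueError):
    """A parameter value violates an operation's precondition."""


class FormatError(PoreScanError, ValueError):
    """A file could not be parsed; the message carries line context."""


class ShapeError(PoreScanError, ValueError):
    """Mismatched atom counts / array shapes between related objects."""


class EmptyInputError(PoreScanError, ValueError):
    """A structure, trajectory or tuple set with no content."""


class DegenerateGeometryError(PoreScanError, ValueError):
    """Too few non-collinear atoms for a unique rigid superposition."""


class InsufficientDataError(PoreScanError, ValueError):
    """A series is too short for the requested analysis window."""


class UndefinedFractionError(PoreScanError, ZeroDivisionError):
    """Fraction of native contacts requested against an empty contact set."""


class DegenerateScalingError(PoreScanError, ValueError):
    """Scaling requested on fewer than two distinct tuples."""


class DegenerateKDEError(PoreScanError, ValueError):
    """Kernel density estimate requested on a singleton/degenerate cluster."""


class StageError(PoreScanError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
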