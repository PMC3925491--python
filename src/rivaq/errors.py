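"""Exception types shared across the package.

All inherit from :class:`RivaqError` so callers (and the CLI) can catch
data-level problems in one place and map them to exit status 1.
"""


class RivaqError(ValueError):
    """Base class for all data/geometry errors raised by rivaq."""


class DegeneratePointSetError(RivaqError):
    """Fewer than 3 points, or all points collinear: no surface exists."""


class AmbiguousElevationError(RivaqError):
    """Two input points share (x, y) but carry different z."""


class OutsideSurfaceError(RivaqError):
    """A query point falls outside the convex hull of the surface."""


class UndefinedFlowDirectionError(RivaqError):
    """Aspect requested on a flat (zero-slope) triangle."""


class SchemaError(RivaqError):
    """Input file is missing a required column."""


class ParseError(RivaqError):
    """A row of an input file could not be parsed; message names the line."""
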