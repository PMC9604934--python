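"""Exception hierarchy.

All failures raised by glenax derive from :class:`GlenaxError` so callers can
distinguish domain failures (bad geometry, malformed input) from programming
errors.
"""


class GlenaxError(Exception):
    """Base class for all glenax-specific failures."""


class ValidationError(GlenaxError):
    """An input object violates one of its declared invariants."""


class DegenerateGeometryError(GlenaxError):
    """A geometric fit or construction received degenerate input
    (collinear points for a plane, coplanar points for a sphere, a
    direction parallel to a projection plane's normal, ...)."""


class DegenerateDataError(GlenaxError):
    """A statistic is undefined on the given sample (constant sample,
    zero between-case variance, ...)."""
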