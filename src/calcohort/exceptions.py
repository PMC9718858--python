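"""Exception hierarchy for calcohort.

All errors raised deliberately by the library derive from
:class:`CalcohortError` so callers can catch pipeline failures without
masking programming errors.
"""


class CalcohortError(Exception):
    """Base class for all calcohort errors."""


class InvalidParameterError(CalcohortError, ValueError):
    """A parameter violates its documented precondition."""


class InvalidInputError(CalcohortError, ValueError):
    """Input data are malformed (NaNs, missing tags, schema violations)."""


class ShapeError(CalcohortError, ValueError):
    """Array arguments have incompatible shapes or lengths."""


class DegenerateBaselineError(CalcohortError, ValueError):
    """The rolling fluorescence baseline is non-positive somewhere.

    A non-positive F0 makes dF/F = (F - F0)/F0 undefined and marks the
    trace as unusable rather than silently producing garbage.
    """
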