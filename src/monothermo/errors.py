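"""Exception hierarchy for monolayer isotherm analysis.

Argument-contract violations (bad window sizes, nonpositive areas, ...)
raise plain :class:`ValueError`; everything data- or range-related gets a
dedicated subclass of :class:`MonolayerError` so pipelines can report
per-file failures without string matching.
"""


class MonolayerError(Exception):
    """Base class for all monothermo-specific errors."""


class ParseError(MonolayerError):
    """An isotherm file could not be parsed into numeric columns."""


class ValidationError(MonolayerError):
    """An isotherm or series violates a structural invariant."""


class PressureRangeError(MonolayerError):
    """A requested surface pressure lies outside the covered branch."""


class NoLiftOffError(MonolayerError):
    """Surface pressure never rises measurably above zero."""


class NoLinearSegmentError(MonolayerError):
    """No quasi-linear condensed segment qualifies for extrapolation."""


class NoCollapseError(MonolayerError):
    """No collapse signature (plateau, drop or kink) is present."""


class InsufficientDataError(MonolayerError):
    """Too few points (or too few detected features) for the operation."""


class ManifestError(MonolayerError):
    """A mixture-series manifest is incomplete or inconsistent."""


class ConfigError(MonolayerError):
    """A scenario / run configuration is invalid."""
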