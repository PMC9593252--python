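"""Exception hierarchy for the ncd package.

All errors derive from :class:`NcdError` (and from ``ValueError`` so callers
that only know the standard library still catch them sensibly).
"""


class NcdError(ValueError):
    """Base class for all ncd errors."""


class FormatError(NcdError):
    """A file or table does not have the required structure (e.g. missing column)."""


class ParseError(NcdError):
    """A value in an input file could not be parsed (carries the row index)."""


class ParameterError(NcdError):
    """A parameter is out of its admissible range."""


class GeometryError(NcdError):
    """Windows/ROIs are inconsistent (mismatched or non-intersecting)."""


class InsufficientDataError(NcdError):
    """Too few points/observations for the requested statistic."""


class DegenerateDataError(NcdError):
    """The data are degenerate for the requested statistic (e.g. zero variance)."""
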