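"""Exception hierarchy for the pipeline.

All errors raised by this package derive from :class:`EegTiError`, so callers
can catch one type at the CLI boundary while tests target specific failures.
"""


class EegTiError(Exception):
    """Base class for all package errors."""


class FormatError(EegTiError):
    """A file does not conform to the expected on-disk format."""


class ParseError(FormatError):
    """A delimited-text file contains a malformed cell or row."""


class ParameterError(EegTiError, ValueError):
    """An argument is outside its valid domain."""


class DomainError(EegTiError, ValueError):
    """A numeric input makes the requested transform undefined (e.g. log of 0)."""


class MissingBandError(EegTiError, KeyError):
    """A band required by an index formula is absent from the power table."""


class NoCleanEpochsError(EegTiError):
    """Every epoch of a recording was rejected; spectral estimation refused."""


class UndefinedRatioError(EegTiError):
    """Relative power requested where the denominator (total power) is zero."""


class InsufficientDataError(EegTiError):
    """Too few non-missing observations for the requested statistic."""


class AlignmentError(EegTiError):
    """Two paired samples do not share the same subject set."""


class DegenerateCaseError(EegTiError):
    """A statistic is undefined for this input (e.g. zero-variance differences)."""
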