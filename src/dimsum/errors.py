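"""Exception hierarchy.

``DimsumError`` is the common base. ``DataError`` marks problems with user
data (malformed files, incomparable inputs, absent structure) and maps to
CLI exit code 2; usage/configuration mistakes map to exit code 1.
"""


class DimsumError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(DimsumError, ValueError):
    """Invalid parameter or configuration value."""


class CapacityError(DimsumError):
    """Problem size exceeds the exact solver's cap; use the stochastic search."""


class DataError(DimsumError):
    """Base class for errors caused by the input data."""


class InvalidEventError(DataError, IndexError):
    """Inversion event indices fall outside the current arrangement."""


class IncomparableArrangementsError(DataError):
    """Two arrangements do not share the same block label set."""


class BlockTSVParseError(DataError):
    """Malformed block/gene-order TSV; carries a 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class NoAnchorsError(DataError):
    """No shared single-copy genes between two gene orders."""


class NoInvertedRepeatError(DataError):
    """No inverted repeat of the required length; non-quadripartite plastome."""


class InconsistencyError(DataError):
    """A quadripartite map does not fit the record it is applied to."""


class FeatureNotFoundError(DataError, KeyError):
    """Named gene absent from a plastome record."""
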