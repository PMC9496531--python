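"""Exception hierarchy for liqspec.

All errors derive from :class:`LiqSpecError` so callers can catch the
package's failures with a single except clause; most also derive from
``ValueError`` because they signal invalid input rather than broken state.
"""


class LiqSpecError(ValueError):
    """Base class for all liqspec errors."""


class SpectrumParseError(LiqSpecError):
    """A spectrum CSV file could not be parsed.

    Carries ``line_number`` (1-based) of the offending row when known.
    """

    def __init__(self, message: str, line_number: int | None = None):
        super().__init__(message)
        self.line_number = line_number


class InvalidSpectrumError(LiqSpecError):
    """A spectrum violates a structural invariant (length, finiteness, range)."""


class GridError(LiqSpecError):
    """Problem with a wavenumber grid (non-monotone, too sparse, ...)."""


class GridMismatchError(GridError):
    """Replicates do not share a common wavenumber grid."""


class SpectralRangeError(GridError):
    """A requested wavenumber or region lies outside the spectrum's span."""


class SchemaError(LiqSpecError):
    """A tabular input is missing required columns."""


class DomainError(LiqSpecError):
    """A value is outside its physical/mathematical domain (e.g. negative mass)."""


class ConfigurationError(LiqSpecError):
    """Invalid configuration: unknown analyte, bad anchor region, bad schema."""


class InsufficientAnchorError(ConfigurationError):
    """An anchor region contains fewer than two grid points."""


class InsufficientDataError(LiqSpecError):
    """Too few points/levels/pairs for the requested fit or comparison."""


class InvalidCurveError(LiqSpecError):
    """A calibration fit produced a non-positive slope (no usable response)."""


class NotBaselinedError(LiqSpecError):
    """An operation requiring baseline-corrected input received a raw spectrum."""
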