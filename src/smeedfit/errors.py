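"""Exception hierarchy for smeedfit."""


class SmeedFitError(Exception):
    """Base class for all smeedfit errors."""


class PanelFormatError(SmeedFitError):
    """Raised when a country-year panel file is malformed or violates the
    panel contract (missing columns, duplicate country-year rows)."""


class InsufficientDataError(SmeedFitError):
    """Raised when a series has too few usable observations to fit
    (fewer than 3 transformed points)."""


class SingularFitError(SmeedFitError):
    """Raised when the regression design is degenerate (all motorization
    values identical)."""


class NoInteriorPeakError(SmeedFitError):
    """Raised when a peak quantity (maximum mortality, peak motorization)
    is requested for a fit with b <= 0, where the curve is monotone and
    has no interior maximum."""


class ConfigError(SmeedFitError):
    """Raised for invalid synthetic-data generator configuration."""
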