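"""Exception types shared across the package."""


class MicellabError(Exception):
    """Base class for package-specific errors."""


class ConfigurationError(MicellabError):
    """A parameter set or preset is inconsistent or unknown."""


class DomainError(MicellabError, ValueError):
    """An input value lies outside the physically meaningful domain."""


class CalibrationError(MicellabError):
    """Calibration could not be constructed or applied."""


class WeightingError(MicellabError):
    """Histogram weighting contract violated (e.g. double mass-weighting)."""


class FitError(MicellabError):
    """A model fit failed to converge or the design is degenerate."""


class SchemaError(MicellabError):
    """A tabular input does not match the expected schema."""
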