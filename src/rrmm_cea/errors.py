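"""Exception hierarchy for the decision model."""


class RRMMCEAError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RRMMCEAError):
    """A required configuration key is missing or the file cannot be parsed."""


class ValidationError(RRMMCEAError):
    """A parameter or derived quantity violates a model invariant."""


class FittingError(RRMMCEAError):
    """A sampling distribution cannot be fitted to the requested moments."""


class CalibrationError(RRMMCEAError):
    """Root finding for baseline hazards or cost scales failed."""


class EngineError(RRMMCEAError):
    """Malformed inputs to the cohort engine (dimension/stochasticity)."""


class UnsupportedStrategyError(RRMMCEAError):
    """A treatment arm with no known dosing calendar was requested."""


class ComparisonError(RRMMCEAError):
    """Two arm results cannot be compared (mismatched settings)."""
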