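"""Exception hierarchy shared across the package."""


class RadarVitalsError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(RadarVitalsError, ValueError):
    """A parameter or object violates its declared constraints."""


class DomainError(RadarVitalsError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class DetectionError(RadarVitalsError, RuntimeError):
    """Target detection failed (degenerate or empty input)."""


class EstimationError(RadarVitalsError, RuntimeError):
    """An estimator could not produce a value from the given data."""
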