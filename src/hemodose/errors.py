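"""Exception hierarchy shared across the package."""


class HemodoseError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(HemodoseError):
    """A run or model configuration is incomplete or inconsistent."""


class ValidationError(HemodoseError):
    """An object violates one of its structural invariants."""


class FormatError(HemodoseError):
    """A file does not conform to the expected on-disk dialect."""


class DomainError(HemodoseError):
    """An argument lies outside the mathematical domain of an operation."""


class UndefinedMetricError(HemodoseError):
    """A dose metric is undefined for the given distribution (e.g. D95% = 0)."""


class IntegrityError(HemodoseError):
    """Serialized cohort data does not match its manifest."""
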