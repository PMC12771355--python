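"""Exception hierarchy shared across the package."""


class CocompareError(ValueError):
    """Base class for all package-specific errors."""


class DomainError(CocompareError):
    """An argument lies outside the mathematical domain of an operation."""


class SchemaError(CocompareError):
    """An input table does not conform to the expected column schema."""


class IntegrityError(CocompareError):
    """An input table violates a uniqueness or referential constraint."""


class InsufficientDataError(CocompareError):
    """Too few observations to compute the requested statistic."""
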