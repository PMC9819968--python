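"""Exception hierarchy for validation, schema and configuration failures."""


class EcoFootError(Exception):
    """Base class for all package errors."""


class SchemaError(EcoFootError):
    """A tabular input is structurally malformed (missing/unknown columns)."""


class ValidationError(EcoFootError, ValueError):
    """A value violates a domain invariant (negative consumption, k > n, ...)."""


class ConfigurationError(EcoFootError):
    """Constant tables and records are mutually inconsistent (missing yield, ...)."""


class UndefinedDepthError(EcoFootError, ZeroDivisionError):
    """Footprint depth is undefined because total carrying capacity is zero."""
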