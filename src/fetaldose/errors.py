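"""Exception hierarchy shared across the package."""


class FetalDoseError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(FetalDoseError, ValueError):
    """A CSV input is missing required columns or has the wrong shape."""


class TableValidationError(FetalDoseError, ValueError):
    """A coefficient table violates one of its invariants."""


class InputError(FetalDoseError, ValueError):
    """A physical quantity supplied by the caller is out of its valid domain."""


class ConfigurationError(FetalDoseError, ValueError):
    """A calibration or configuration object lacks a field the operation needs."""


class UnknownKeyError(FetalDoseError, KeyError):
    """A projection key or scanner model is not present in the coefficient store."""


class RangeError(FetalDoseError, ValueError):
    """A scan range is inverted or falls outside the phantom."""
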