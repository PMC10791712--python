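"""Exception hierarchy for the emwater pipeline."""


class EmwaterError(Exception):
    """Base class for all package errors."""


class SchemaError(EmwaterError):
    """Input table is missing required columns or has unparseable fields."""


class ValidationError(EmwaterError):
    """Records violate a domain invariant (range, uniqueness, unknown code)."""


class UndefinedChangeError(EmwaterError):
    """Percent change requested against a zero baseline."""


class DegenerateTestError(EmwaterError):
    """A statistical test has no sampling variability (all values tied)."""


class ConfigurationError(EmwaterError):
    """Regulatory / classification configuration is incomplete or inconsistent."""
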