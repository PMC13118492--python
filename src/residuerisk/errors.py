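"""Exception types shared across the package."""


class ResidueRiskError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(ResidueRiskError):
    """An input table is missing required columns or is otherwise malformed."""


class ValidationError(ResidueRiskError):
    """An input value violates a domain invariant (sign, range, uniqueness)."""


class AnalyteLookupError(ResidueRiskError, KeyError):
    """An analyte is absent from the reference table or monitoring panel."""
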