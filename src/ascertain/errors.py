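"""Exception hierarchy for cohort validation and configuration problems."""


class AscertainError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(AscertainError, ValueError):
    """A record or value violates a domain invariant (bad date, bad code system...)."""


class SchemaError(AscertainError):
    """An input table does not match the declared column mapping."""


class ReferentialError(AscertainError):
    """An event or registry row refers to a person absent from the person table."""


class ConfigurationError(AscertainError):
    """An indicator, window or generator configuration is invalid."""
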