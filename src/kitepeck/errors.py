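"""Exception hierarchy for kitepeck."""


class KitepeckError(Exception):
    """Base class for all kitepeck errors."""


class SchemaError(KitepeckError):
    """An input table violates its declared schema (missing column, bad value)."""


class ParseError(SchemaError):
    """A date/time field could not be parsed."""


class ReferentialError(KitepeckError):
    """A cross-reference between tables does not resolve (unknown id, self-peck)."""


class ConfigError(KitepeckError):
    """A configuration value is missing or invalid (e.g. prey weight table)."""


class FitError(KitepeckError):
    """A model could not be fitted on the provided data."""


class DegenerateDesignError(FitError):
    """The design matrix is degenerate (e.g. a single age-difference value)."""
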