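"""Shared exception types for the stageshift package."""


class StageshiftError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(StageshiftError, ValueError):
    """An argument violates a documented precondition."""


class InvalidGeometryError(StageshiftError, ValueError):
    """A polygon is degenerate, self-intersecting or otherwise unusable."""


class SchemaError(StageshiftError, ValueError):
    """Tabular input does not match the expected schema."""


class ConfigurationError(StageshiftError, ValueError):
    """Mutually inconsistent or unknown configuration options."""


class NewickParseError(StageshiftError, ValueError):
    """A Newick string could not be parsed into a valid tree."""
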