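"""Exception hierarchy.

Validation errors (bad data) and configuration errors (bad setup) are kept
distinct because the CLI maps them to different exit codes (2 and 3).
"""


class AeropollenError(Exception):
    """Base class for all package errors."""


class ValidationError(AeropollenError):
    """Input data violates a domain invariant."""

    exit_code = 2


class SchemaError(ValidationError):
    """A required column is missing from an input table."""


class DuplicateRecordError(ValidationError):
    """The same (site, taxon, date) appears more than once."""


class DegenerateSiteError(ValidationError):
    """A site has zero total pollen and cannot be expressed as percentages."""


class ConfigurationError(AeropollenError):
    """Invalid sampler spec, mapping, or pipeline configuration."""

    exit_code = 3
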