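"""Exception hierarchy for the pipeline.

Every error raised by the package derives from :class:`SertnetError`, so
callers (and the CLI) can catch one type. Subclasses distinguish the three
failure families a user can actually act on: malformed input tables,
inconsistent study designs, and numerically undefined statistics.
"""


class SertnetError(Exception):
    """Base class for all package errors."""


class SchemaError(SertnetError):
    """An input table is missing a required column or uses unknown labels."""


class ParseError(SertnetError):
    """A cell could not be parsed as the required numeric type."""


class IntegrityError(SertnetError):
    """Duplicate (subject, condition) rows or other dataset-level violations."""


class DesignError(SertnetError):
    """A contrast or permutation scheme is inconsistent with the cohorts."""


class ConfigurationError(SertnetError):
    """Invalid configuration values (region mismatch, missing coordinates...)."""


class UndefinedCorrelationError(SertnetError):
    """A correlation is undefined (zero rank variance, too few subjects)."""
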