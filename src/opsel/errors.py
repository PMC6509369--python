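"""Exception hierarchy for opsel.

All package-specific failures derive from :class:`OpselError` so callers can
catch one base class at pipeline level.
"""


class OpselError(Exception):
    """Base class for all opsel errors."""


class ConfigurationError(OpselError):
    """Invalid island/truth/run configuration (bad dimensions, infeasible rates)."""


class SchemaError(OpselError):
    """Input table is missing required columns or has the wrong dtypes."""


class IntegrityError(OpselError):
    """Data violate a structural assumption (e.g. a band with two dominant males)."""


class UndefinedStatisticError(OpselError):
    """A selection statistic is undefined (mean mating success of zero)."""


class FitError(OpselError):
    """Model fitting failed: singular design, non-convergence, or AICc undefined."""
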