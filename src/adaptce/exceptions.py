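"""Exception hierarchy for adaptce.

All errors derive from :class:`AdaptceError` (a ``ValueError``) so callers can
catch the package's failures with a single except clause while standard
``ValueError`` semantics are preserved.
"""


class AdaptceError(ValueError):
    """Base class for all adaptce errors."""


class InvalidParameterError(AdaptceError):
    """A probability, odds ratio, or design constant is outside its domain."""


class InfeasibleCorrelationError(AdaptceError):
    """A correlation lies outside the Frechet-implied feasible range."""


class UndefinedSampleSizeError(AdaptceError):
    """Sample size undefined, e.g. odds ratio equal to 1 (zero log-odds effect)."""


class UnsupportedConfigurationError(AdaptceError):
    """A configuration the methodology does not cover (e.g. unequal ORs across arms)."""


class SchemaError(AdaptceError):
    """An input file violates the documented schema; message names the field."""


class ConfigurationError(AdaptceError):
    """A scenario-grid or run configuration is invalid or empty."""
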