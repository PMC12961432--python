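"""Exception hierarchy for nrlkit.

All nrlkit-specific failures derive from :class:`NrlkitError` so callers
can catch the whole family with one clause. Parse and configuration
problems are ``ValueError`` subclasses; estimation failures (too few
summits, no periodic signal) are runtime conditions of the data, not
programming errors, and derive from ``RuntimeError``.
"""


class NrlkitError(Exception):
    """Base class for all nrlkit errors."""


class ParseError(NrlkitError, ValueError):
    """A line of an input file could not be parsed; message names the line."""


class ValidationError(NrlkitError, ValueError):
    """An input record or parameter violates an invariant."""


class ConfigError(NrlkitError, ValueError):
    """A simulation or run configuration is internally inconsistent."""


class EstimationError(NrlkitError, RuntimeError):
    """An estimator could not produce a result from the given data."""
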