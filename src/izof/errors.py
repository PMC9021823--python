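"""Exception hierarchy for the izof package.

All errors raised by the library derive from :class:`IzofError`, so callers
can catch one type at a pipeline boundary while tests can assert on the
specific failure mode.
"""


class IzofError(Exception):
    """Base class for all izof errors."""


class SchemaError(IzofError):
    """Input table does not conform to the documented cohort schema
    (e.g. a required column is missing)."""


class ValidationError(IzofError):
    """A value violates a documented range, uniqueness or completeness
    invariant; the message names the offending row/field."""


class ConfigurationError(IzofError):
    """A user-supplied configuration object (item key, generator config,
    run config) is malformed; the message names the field."""


class InsufficientPanelError(ValidationError):
    """A judge panel is too small to trim one score from each end and
    retain at least one."""


class EstimabilityError(IzofError):
    """Not enough observations to estimate the requested quantity
    (zone, threshold, classification percentage)."""


class AlignmentError(IzofError):
    """Two participant-indexed collections do not cover the same set of
    participants."""
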