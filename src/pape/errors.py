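"""Exception hierarchy shared across the pipeline stages."""


class PapeError(Exception):
    """Base class for all package errors."""


class InsufficientDataError(PapeError):
    """Too few observations to carry out the requested computation."""


class NoDataError(PapeError):
    """A required data stream is empty."""


class CoverageError(PapeError):
    """Inputs do not cover the time or space being queried (e.g. a missing
    hourly map, or an indoor period outside the activity trace's day)."""


class ConfigurationError(PapeError):
    """Invalid or incomplete configuration (bad fold count, missing baseline
    route, VE value not supplied for a requested activity, ...)."""


class ValidationError(PapeError):
    """Malformed input rows (overlapping trace segments, bad coordinates,
    unknown activity labels, unsorted samples)."""


class IllConditionedError(PapeError):
    """The kriging system remained singular after diagonal regularization."""
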