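"""Exception hierarchy shared across the pipeline.

``ValidationError`` marks a violated precondition or malformed configuration
(CLI exit code 2); ``DataError`` marks inputs that are structurally readable
but scientifically unusable (CLI exit code 3).
"""


class MetabodxError(Exception):
    """Base class for all package errors."""


class ValidationError(MetabodxError, ValueError):
    """A precondition or configuration invariant was violated."""


class DataError(MetabodxError, ValueError):
    """Input data are unusable (wrong shape, missing coverage, degenerate)."""


class NoSignalError(DataError):
    """The predictive weight has no norm: X carries no covariance with y."""
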