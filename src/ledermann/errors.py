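"""Exception hierarchy.

Error classes map one-to-one onto the failure modes of the pipeline stages:
schema/configuration problems, data validation, degenerate designs, and
undefined statistical quantities.  The CLI translates these into distinct
exit codes.
"""


class LedermannError(Exception):
    """Base class for all package errors."""


class SchemaError(LedermannError):
    """Input file does not match the declared schema (missing columns, bad types)."""


class ConfigurationError(LedermannError):
    """Invalid configuration (unknown ill-defined label, infeasible parameters)."""


class DataValidationError(LedermannError):
    """Data violate an invariant (negative counts, mismatched shapes)."""


class InsufficientDataError(LedermannError):
    """Too few areas for the requested regression-based operation."""


class DegenerateDesignError(LedermannError):
    """Regression design is degenerate (e.g. constant ill-defined share)."""


class NoReceivingCauseError(LedermannError):
    """No cause is negatively associated with the ill-defined share; nothing can receive deaths."""


class EmptyResultError(LedermannError):
    """An operation would produce an empty result (e.g. all areas have zero deaths)."""


class UndefinedRateError(LedermannError):
    """A death rate is requested where exposure is zero but deaths are positive."""
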