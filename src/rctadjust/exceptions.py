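"""Exception hierarchy.

All package errors derive from :class:`RctAdjustError` so callers can catch
one base class; the three subclasses distinguish bad configuration, invalid
data, and estimation failures (the distinction drives CLI exit codes).
"""


class RctAdjustError(Exception):
    """Base class for all rctadjust errors."""


class ConfigurationError(RctAdjustError):
    """A config file, column map, or function argument is invalid."""


class ValidationError(RctAdjustError):
    """A dataset violates a TrialDataset invariant."""


class EstimationError(RctAdjustError):
    """An estimator could not produce a valid result (rank deficiency,
    non-convergence, singular sandwich bread, unstable bootstrap, ...)."""
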