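"""Exception hierarchy for the wearload pipeline.

Every stage raises a subclass of :class:`WearloadError`, so callers can
trap pipeline failures without catching unrelated exceptions.
"""


class WearloadError(Exception):
    """Base class for all wearload errors."""


class FormatError(WearloadError):
    """A file does not match the expected CSV dialect (missing column, empty file)."""


class SeriesValidationError(WearloadError):
    """A time series violates its invariants (non-monotone timestamps, ragged channels)."""


class WindowError(WearloadError):
    """A trial is too short for the requested analysis window."""


class CalibrationError(WearloadError):
    """A calibration fit is degenerate (e.g. all voltages identical)."""


class UsageError(WearloadError):
    """An operation was applied to an input in the wrong state (e.g. re-calibrating
    an already-calibrated series, or differentiating a non-uniform grid)."""


class InsufficientDataError(WearloadError):
    """Too few samples or groups for the requested computation."""


class ConvergenceError(WearloadError):
    """A mixed-model fit failed to converge or was singular."""


class DegenerateSampleError(WearloadError):
    """A statistical test received a degenerate (e.g. constant) sample."""
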