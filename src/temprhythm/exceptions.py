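"""Exception hierarchy for temprhythm.

All errors raised by the library derive from :class:`TempRhythmError` so
callers can catch pipeline failures with a single except clause.
"""


class TempRhythmError(Exception):
    """Base class for all temprhythm errors."""


class ConfigurationError(TempRhythmError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class AlignmentError(TempRhythmError, ValueError):
    """An epoch grid that does not align with the requested aggregation bins."""


class InsufficientDataError(TempRhythmError, ValueError):
    """Not enough (complete) data to compute the requested quantity."""


class RankDeficiencyError(TempRhythmError, ValueError):
    """A degenerate design matrix (constant time, collinear covariates, ...)."""


class ConvergenceError(TempRhythmError, RuntimeError):
    """A model fit failed to converge or produced a singular solution."""


class PairingError(TempRhythmError, ValueError):
    """Two series that should be paired element-wise do not match in length."""
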