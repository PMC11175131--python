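"""Exception hierarchy for the gait-stability pipeline.

All errors derive from :class:`GaitStabError` so callers can catch the
package's failures without masking programming errors.
"""


class GaitStabError(Exception):
    """Base class for all gaitstab errors."""


class InvalidSpecError(GaitStabError, ValueError):
    """A cohort/trial specification violates its invariants."""


class DataError(GaitStabError, ValueError):
    """Input data is malformed (non-finite samples, bad shapes)."""


class InvalidParameterError(GaitStabError, ValueError):
    """A tuning parameter is outside its allowed range."""


class NoGaitError(GaitStabError, ValueError):
    """Too few gait peaks were found to delimit any cycle."""


class InsufficientDataError(GaitStabError, ValueError):
    """Not enough cycles/points for the requested computation."""


class EmptyHazardError(GaitStabError, ValueError):
    """No gait cycle overlaps any hazard window."""


class ZeroVarianceError(GaitStabError, ValueError):
    """A correlation was requested on a constant input."""


class NoRecoveryError(GaitStabError, ValueError):
    """The fitted post-hazard trend is not decreasing (a <= 0)."""


class CalibrationError(GaitStabError, RuntimeError):
    """Hazard-magnitude bisection failed to bracket the target."""


class SizeError(GaitStabError, ValueError):
    """Input exceeds a hard size cap (brute-force oracle only)."""
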