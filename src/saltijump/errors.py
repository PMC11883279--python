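"""Exception hierarchy for saltijump.

All package-specific errors derive from :class:`SaltijumpError` so callers
can distinguish pipeline failures from programming errors.
"""


class SaltijumpError(Exception):
    """Base class for all saltijump errors."""


class FormatError(SaltijumpError):
    """A tracked-point or metadata file violates the expected dialect."""


class EmptyTrackError(SaltijumpError):
    """A point track has no finite frames where they are required."""


class CalibrationError(SaltijumpError):
    """Degenerate pixel-to-mm calibration (coincident reference points)."""


class FeasibilityError(SaltijumpError):
    """The requested stance-profile statistics are jointly unattainable."""


class ScheduleError(SaltijumpError):
    """A per-leg extension/lift-off schedule is internally inconsistent."""


class NoMovementError(SaltijumpError):
    """Onset detection found no frame exceeding the noise threshold."""


class NoLiftoffError(SaltijumpError):
    """A tarsal claw never rose above the lift-off height threshold."""


class EventError(SaltijumpError):
    """Jump events are out of range or ordered inconsistently."""


class DegenerateAngleError(SaltijumpError):
    """An angle is requested for a zero-length displacement."""


class DegenerateChainError(SaltijumpError):
    """A leg chain has zero total segment length."""


class IncompleteTrajectoryError(SaltijumpError):
    """The CoM trajectory ends before spanning the platform gap."""


class MeshIntegrityError(SaltijumpError):
    """A triangle mesh is not watertight / consistently oriented."""


class DesignError(SaltijumpError):
    """A statistical design is singular (e.g. only one sex present)."""


class ComparisonError(SaltijumpError):
    """Two model fits cannot be compared (mismatched responses)."""


class SchemaError(SaltijumpError):
    """A results table is missing required columns."""
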