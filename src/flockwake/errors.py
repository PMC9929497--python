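"""Exception hierarchy for flockwake.

All domain errors derive from :class:`FlockwakeError` so callers (and the
CLI) can catch one base class and exit with a diagnostic.
"""


class FlockwakeError(Exception):
    """Base class for all flockwake errors."""


class TrajectoryError(FlockwakeError):
    """Invalid trajectory data (non-monotone time, irregular rate, NaNs)."""


class BoundaryTimestampError(FlockwakeError):
    """Heading requested at a timestamp without both neighbouring samples."""


class DegenerateHeadingError(FlockwakeError):
    """Heading undefined because a horizontal displacement has zero length."""


class MissingSnapshotError(FlockwakeError):
    """A bird has no sample at the requested timestamp."""


class InsufficientDataError(FlockwakeError):
    """Fewer usable snapshots than the analysis requires."""


class ConfigError(FlockwakeError):
    """Inconsistent model or simulation configuration."""


class ParseError(FlockwakeError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class EvaluationError(FlockwakeError):
    """A fuzzy rule references an input variable that was not supplied."""


class AlignmentError(FlockwakeError):
    """Two assignment streams do not cover identical snapshots."""
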