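"""Exception hierarchy.

All user-facing failures derive from :class:`AncacError` so the CLI can map
them onto exit codes (input/format problems vs. undefined computations).
"""


class AncacError(Exception):
    """Base class for all errors raised by this package."""


class DataError(AncacError):
    """Malformed or inconsistent input data (parse errors, bad tables)."""


class IntegrityError(DataError):
    """A dataset invariant is violated (dangling references, duplicates)."""


class BatchFormatError(DataError):
    """A batch-query line does not follow the NAME:FEATURES:COGS grammar."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class UndefinedScoreError(AncacError):
    """A score has no defined value (empty scope or zero denominator)."""

    def __init__(self, message: str, n_skipped: int = 0):
        super().__init__(message)
        self.n_skipped = n_skipped


class SimulationError(AncacError):
    """The synthetic-data generator was given an infeasible specification."""
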