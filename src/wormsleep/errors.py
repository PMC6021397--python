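"""Exception hierarchy shared across the package."""


class WormsleepError(Exception):
    """Base class for all package-specific errors."""


class ShapeMismatchError(WormsleepError):
    """Two frames (or a ROI and a frame) have incompatible dimensions."""


class InsufficientInputError(WormsleepError):
    """Fewer samples/frames than the operation requires."""


class ParameterError(WormsleepError, ValueError):
    """A configuration object violates its invariants."""


class ContractError(WormsleepError):
    """A call violates a documented precondition (e.g. wrong window length)."""


class SequencingError(WormsleepError):
    """Streaming samples arrived out of order."""


class DegenerateInputError(WormsleepError):
    """Input is valid in shape but statistically degenerate (e.g. constant)."""


class ScheduleParseError(WormsleepError):
    """A stimulus schedule file could not be parsed; carries the line number."""

    def __init__(self, message: str, line_no: int | None = None):
        self.line_no = line_no
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)


class LethargusNotFound(WormsleepError):
    """No non-pumping frames exist; distinct from a malformed-input error."""
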