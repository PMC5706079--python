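"""Exception hierarchy for profgram.

All parser errors carry the source path and a 1-based position so that a
user pointed at a malformed profile file can find the offending line.
"""


class ProfgramError(Exception):
    """Base class for all profgram errors."""


class MalformedFileError(ProfgramError):
    """A profile file is structurally invalid (missing tag, terminator, body)."""

    def __init__(self, message: str, path: str = "<stream>", line: int | None = None):
        loc = f"{path}" + (f":{line}" if line is not None else "")
        super().__init__(f"{loc}: {message}")
        self.path = path
        self.line = line


class MalformedRowError(ProfgramError):
    """A single profile row is invalid; ``position`` is 1-based."""

    def __init__(self, message: str, path: str = "<stream>", position: int | None = None):
        loc = f"{path}" + (f" (position {position})" if position is not None else "")
        super().__init__(f"{loc}: {message}")
        self.path = path
        self.position = position


class InvalidInputError(ProfgramError):
    """An operation received input violating its preconditions."""


class InconsistentInputError(ProfgramError):
    """Two inputs that must agree (instance id, origin, dimension) do not."""


class UntrainableError(ProfgramError):
    """The training set cannot produce a classifier (e.g. a single class)."""


class ModelFormatError(ProfgramError):
    """A model file is corrupt, truncated, or has an unsupported version."""


class UndefinedMetricError(ProfgramError):
    """A metric is undefined for the given inputs (e.g. single-class auROC)."""
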