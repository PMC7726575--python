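"""Exception hierarchy shared across the package."""


class CrimescapeError(Exception):
    """Base class for package-specific errors."""


class ConfigError(CrimescapeError, ValueError):
    """A configuration object violates its invariants."""


class FormatError(CrimescapeError, ValueError):
    """An input file does not follow the expected schema."""


class GeometryError(CrimescapeError, ValueError):
    """A polygon or polyline is invalid for the requested operation."""


class DegenerateStatisticError(CrimescapeError, ValueError):
    """A statistic is undefined for the given input (e.g. zero variance)."""


class StageError(CrimescapeError, RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause!r}")
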