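"""Exception hierarchy shared across the package.

Validation-type errors derive from :class:`ValidationError` so the CLI can map
them to exit code 1; anything else surfacing from a stage maps to exit code 2.
"""


class CenfiberError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CenfiberError, ValueError):
    """Malformed input data or inconsistent records."""


class ParameterError(ValidationError):
    """A parameter value outside its documented domain."""


class CoordinateError(ValidationError):
    """Genomic coordinates outside their chromosome or inverted."""


class LayoutError(CenfiberError, RuntimeError):
    """Chromatin layout constraints cannot be satisfied."""


class ConsistencyError(ValidationError):
    """Cross-referenced records disagree (e.g. footprint without its fiber)."""


class FormatError(ValidationError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f"{path}:{line}: " if line is not None else f"{path}: "
        super().__init__(loc + message)
        self.path = path
        self.line = line


class MedianUndefinedError(CenfiberError):
    """A survival curve never crosses the requested probability."""


class PipelineError(CenfiberError, RuntimeError):
    """A pipeline stage failed; names the stage and chains the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
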