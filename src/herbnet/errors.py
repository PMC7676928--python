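"""Exception hierarchy used across the package."""


class HerbnetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HerbnetError):
    """A file does not conform to its declared format.

    Carries an optional line number so parse failures can be located.
    """

    def __init__(self, message: str, *, path=None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        elif line is not None:
            loc += f" [line {line}]"
        super().__init__(message + loc)


class ValidationError(HerbnetError):
    """Input values violate a documented precondition."""


class ConfigError(HerbnetError):
    """A pipeline configuration is missing or inconsistent."""


class PipelineError(HerbnetError):
    """A pipeline stage failed; names the stage and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
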