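"""Exception hierarchy for the cfig pipeline."""


class CfigError(Exception):
    """Base class for all cfig errors."""


class ParseError(CfigError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        super().__init__(message + loc)


class ValidationError(CfigError):
    """Input data violates a documented invariant."""


class ConfigError(CfigError):
    """A configuration field is out of its documented range."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class StageError(CfigError):
    """A pipeline stage failed; names the stage and chains the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
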