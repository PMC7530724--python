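"""Exception hierarchy for the xgage pipeline."""


class XgageError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(XgageError):
    """Invalid configuration (simulation, rule, or run config)."""


class MissingControlsError(XgageError):
    """Control-spot signals required but absent or empty."""


class DesignError(XgageError):
    """Treatment design inconsistent with a requested contrast."""


class ParseError(XgageError):
    """Malformed input file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class AnnotationMismatchError(XgageError):
    """A term id was not found in the ontology graph."""


class InvalidInputError(XgageError):
    """Empty or out-of-domain input to a statistical routine."""


class UndefinedFractionError(XgageError):
    """Overlap fraction requested with a zero denominator."""


class PipelineError(XgageError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
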