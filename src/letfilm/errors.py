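"""Exception hierarchy shared across the package."""


class LetfilmError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LetfilmError):
    """A material, element or parameter is missing or inconsistent."""


class FormatError(LetfilmError):
    """A delimited input file violates its dialect."""


class RangeError(LetfilmError):
    """A requested value lies outside the supported/tabulated range."""


class AlignmentError(LetfilmError):
    """Two binned objects do not share compatible binning or metadata."""


class PipelineStageError(LetfilmError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
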