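"""Exception hierarchy shared across the package.

``ParameterError`` marks caller mistakes (bad flags, infeasible settings);
``DataError`` marks problems in the input data itself (zero-variance genes,
missing conditions); ``PipelineError`` wraps a stage failure with the stage
name so orchestration errors are attributable.
"""


class DcgnetError(Exception):
    """Base class for all package errors."""


class ParameterError(DcgnetError, ValueError):
    """A parameter is outside its documented domain or infeasible."""


class DataError(DcgnetError, ValueError):
    """Input data violates a precondition (shape, variance, labels...)."""


class PipelineError(DcgnetError, RuntimeError):
    """A pipeline stage failed; message carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
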