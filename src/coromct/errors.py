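"""Exception types shared across the pipeline."""


class CoromctError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(CoromctError, ValueError):
    """A physical or geometric parameter is out of its valid range."""


class GatingError(CoromctError, RuntimeError):
    """Intrinsic gating failed (e.g. no spectral peak above the noise floor)."""


class CoverageError(CoromctError, RuntimeError):
    """Angular coverage is insufficient for filtered backprojection."""


class PipelineError(CoromctError, RuntimeError):
    """A pipeline stage was invoked before its upstream artifacts exist."""
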