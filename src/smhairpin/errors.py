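"""Exception hierarchy shared across the pipeline."""


class SMHairpinError(Exception):
    """Base class for all package errors."""


class ParameterError(SMHairpinError, ValueError):
    """Invalid generator or analysis parameters."""


class FitError(SMHairpinError, RuntimeError):
    """A model fit failed to converge or the input is degenerate."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class FormatError(SMHairpinError, ValueError):
    """A file does not conform to the expected on-disk format."""


class AnalysisError(SMHairpinError, RuntimeError):
    """The input data cannot be analysed (saturated trace, zero events, ...)."""
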