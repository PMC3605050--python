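"""Exception hierarchy."""


class ClineKitError(Exception):
    """Base class for all clinekit errors."""


class ValidationError(ClineKitError, ValueError):
    """Invalid parameters, data, or configuration."""


class FitError(ClineKitError, RuntimeError):
    """Optimization failed; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []
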