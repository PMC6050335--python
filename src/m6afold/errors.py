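"""Exception types shared across the package."""


class M6AFoldError(Exception):
    """Base class for package errors."""


class ValidationError(M6AFoldError, ValueError):
    """Invalid input data (sequence alphabet, curve shape, structure consistency...)."""


class ParseError(M6AFoldError, ValueError):
    """Malformed input file; carries line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class FitError(M6AFoldError, RuntimeError):
    """Nonlinear fit failed to converge; carries the best residual seen."""

    def __init__(self, message: str, best_residual: float | None = None):
        self.best_residual = best_residual
        super().__init__(message)


class TruncationError(M6AFoldError, RuntimeError):
    """Suboptimal enumeration exceeded the configured structure-count guard."""

    def __init__(self, message: str, count: int):
        self.count = count
        super().__init__(message)
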