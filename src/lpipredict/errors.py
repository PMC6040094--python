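"""Exception hierarchy shared across the package."""


class LpiError(Exception):
    """Base class for all package-specific errors."""


class DataError(LpiError):
    """Malformed, empty, or inconsistent input data."""


class ParseError(DataError):
    """A line of an input file could not be parsed."""

    def __init__(self, path, lineno: int, message: str):
        self.path = path
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


class AlphabetError(DataError):
    """Sequence characters outside the declared alphabet, or a scoring
    scheme applied to the wrong kind of sequence."""


class DegenerateSequenceError(DataError):
    """A sequence whose self-alignment score is zero cannot be normalized."""


class ConvergenceError(LpiError):
    """Iteration limit reached before the convergence criterion was met."""

    def __init__(self, message: str, residual: float | None = None):
        self.residual = residual
        super().__init__(message)


class DivergenceError(LpiError):
    """The optimizer produced a non-finite objective."""
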