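"""Exception hierarchy for the fracz package."""


class FraczError(Exception):
    """Base class for all fracz errors."""


class InvalidParameterError(FraczError, ValueError):
    """A model parameter violates its admissible range."""


class InvalidSpecError(FraczError, ValueError):
    """A model specification is structurally invalid."""


class DomainError(FraczError, ValueError):
    """An operator or scaling factor was evaluated outside its domain."""


class DataError(FraczError, ValueError):
    """Measured/simulated spectrum data are unusable (NaN, mismatch, ...)."""


class ParseError(FraczError, ValueError):
    """A file could not be parsed; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class NoSolutionError(FraczError, ArithmeticError):
    """A root search failed; carries the bracket and the final residual."""

    def __init__(self, message: str, bracket: tuple[float, float], residual: float):
        self.bracket = bracket
        self.residual = residual
        super().__init__(
            f"{message} (bracket=[{bracket[0]:g}, {bracket[1]:g}], "
            f"residual={residual:g})"
        )
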