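"""Exception hierarchy shared across the package."""


class RamanoiseError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(RamanoiseError, ValueError):
    """An operation received an invalid numeric parameter (e.g. w <= 0)."""


class ConfigError(RamanoiseError, ValueError):
    """A configuration object violates its invariants."""


class ShapeError(RamanoiseError, ValueError):
    """Array shapes or lengths are incompatible."""


class ParseError(RamanoiseError, ValueError):
    """A text or HDF5 input could not be parsed; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class FitError(RamanoiseError, RuntimeError):
    """A model or curve fit failed to produce a usable result."""
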