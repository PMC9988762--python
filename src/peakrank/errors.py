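"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2, every other ``PeakrankError``
(data/validation problems) to exit code 3.
"""


class PeakrankError(Exception):
    """Base class for all package errors."""


class ConfigError(PeakrankError):
    """Invalid configuration (bad value, unknown key, inconsistent block)."""


class ValidationError(PeakrankError):
    """A domain object violates one of its invariants."""


class DataError(PeakrankError):
    """Input data is structurally valid but unusable for the requested operation."""


class BedParseError(DataError):
    """A BED line could not be parsed; carries file path and 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


class PlacementError(DataError):
    """The simulated genome is too small to place the requested genes."""
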