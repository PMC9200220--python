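"""Typed exceptions shared across the package."""


class VScreenError(Exception):
    """Base class for all package errors."""


class ConfigError(VScreenError):
    """Invalid configuration or precondition violation."""


class MoleculeParseError(VScreenError):
    """A molecular record could not be parsed.

    Carries the identifier of the offending record when known.
    """

    def __init__(self, message: str, record_id: str | None = None):
        super().__init__(message)
        self.record_id = record_id


class PDBParseError(VScreenError):
    """A PDB record could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        super().__init__(message)
        self.line_number = line_number


class EmptySentenceError(VScreenError):
    """A substructure sentence with no tokens cannot be embedded."""


class ShapeError(VScreenError):
    """Array shape does not match the model contract."""


class UndefinedMetricError(VScreenError):
    """A metric is undefined for the given inputs (e.g. zero denominator)."""
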