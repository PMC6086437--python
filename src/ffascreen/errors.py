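"""Exception hierarchy for the screening pipeline.

Every stage raises a subclass of :class:`FFAScreenError`, so callers (and the
CLI) can distinguish pipeline failures from programming errors.
"""


class FFAScreenError(Exception):
    """Base class for all package errors."""


class PanelSchemaError(FFAScreenError):
    """Panel table is missing a required column or has a malformed header."""


class PanelValueError(FFAScreenError):
    """A panel field holds a value outside its allowed vocabulary."""


class CrossReferenceError(FFAScreenError):
    """Panel table and panel FASTA disagree about which criteria exist."""


class PanelValidationError(FFAScreenError):
    """A loaded panel violates one or more structural invariants."""


class EvidenceFormatError(FFAScreenError):
    """A homology/domain evidence line could not be parsed."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class ConfigurationError(FFAScreenError):
    """Inputs are individually valid but mutually inconsistent."""


class BoundaryUndefinedError(FFAScreenError):
    """K-means put the positive reference strains into different clusters."""
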