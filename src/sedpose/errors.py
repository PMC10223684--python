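"""Exception hierarchy shared across sedpose modules."""


class SedposeError(Exception):
    """Base class for all sedpose-specific errors."""


class ParseError(SedposeError):
    """A delimited-text input could not be parsed (names the offending row)."""


class DataError(SedposeError):
    """Input data violate a structural invariant (e.g. non-increasing timestamps)."""


class SchemaError(SedposeError):
    """An annotation/bout table violates its schema (labels, interval order)."""


class LengthError(SedposeError):
    """A series is too short for the requested operation."""


class TapDetectionError(SedposeError):
    """Fewer synchronisation taps were found than expected.

    Attributes
    ----------
    found : int
        Number of qualifying tap events that were detected.
    """

    def __init__(self, message: str, found: int = 0):
        super().__init__(message)
        self.found = found
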