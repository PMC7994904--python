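"""Exception hierarchy shared across the package."""


class ScreenError(Exception):
    """Base class for all dracoscreen errors."""


class FormatError(ScreenError):
    """A file could not be parsed as the expected format."""


class ValidationError(ScreenError):
    """Parsed data violates a structural invariant."""


class ParameterError(ScreenError, ValueError):
    """A function argument is outside its valid domain."""


class PlateError(ScreenError):
    """A viability plate is unusable (e.g. non-positive vehicle signal)."""
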