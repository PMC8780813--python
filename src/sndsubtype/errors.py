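"""Exception hierarchy shared across the package."""


class SndError(Exception):
    """Base class for all package errors."""


class FormatError(SndError, ValueError):
    """A file violates the expected tab-delimited dialect."""


class ParseError(FormatError):
    """A cell failed to parse; carries row/column coordinates in the message."""


class ArgumentError(SndError, ValueError):
    """An operation received an argument outside its contract."""


class ModelFormatError(SndError, ValueError):
    """A serialized model file is corrupt, mistyped or of an unknown version."""
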