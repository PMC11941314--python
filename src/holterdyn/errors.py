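"""Exception hierarchy for holterdyn.

All package-specific failures derive from :class:`HolterdynError` so callers
(and the CLI) can catch one base class.
"""


class HolterdynError(Exception):
    """Base class for all holterdyn errors."""


class FormatError(HolterdynError):
    """A file does not conform to the expected dialect (missing/duplicate columns)."""


class ValidationError(HolterdynError):
    """Input parsed but violates a data invariant (e.g. non-increasing time)."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class EmptyInputError(HolterdynError):
    """An operation that requires data received none."""


class DomainError(HolterdynError):
    """A scalar argument is outside its mathematical domain."""


class ConfigurationError(HolterdynError):
    """Ranges/bands configuration is inconsistent with itself or with the data."""
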