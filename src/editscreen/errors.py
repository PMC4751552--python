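"""Exception hierarchy shared across the pipeline."""


class EditScreenError(Exception):
    """Base class for all package errors."""


class FormatError(EditScreenError):
    """A file does not conform to its declared format."""


class ValidationError(EditScreenError):
    """Parsed data violates a structural invariant."""


class UsageError(EditScreenError):
    """An operation was called with inconsistent arguments."""
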