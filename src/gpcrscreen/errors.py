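"""Exception types shared across the package."""


class GpcrScreenError(Exception):
    """Base class for package errors."""


class ValidationError(GpcrScreenError):
    """Raised when an input table, record or configuration fails validation."""
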