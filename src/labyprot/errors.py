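"""Typed exceptions raised by table readers and validators."""


class LabyprotError(Exception):
    """Base class for all package errors."""


class FormatError(LabyprotError, ValueError):
    """A file could not be parsed (wrong column count, non-numeric field, ...)."""


class ValidationError(LabyprotError, ValueError):
    """Parsed content violates a structural invariant (duplicate ids, orphan samples, ...)."""


class ConfoundedDesignError(ValidationError):
    """Batch and biological group structure cannot be separated."""
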