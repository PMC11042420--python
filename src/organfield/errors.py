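"""Exception taxonomy shared across readers and validators."""


class OrganFieldError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(OrganFieldError):
    """A required column or structural element is missing or malformed."""


class ValidationError(OrganFieldError):
    """A value violates a documented range or consistency constraint."""


class ConflictError(OrganFieldError):
    """Two rows disagree about the annotation of the same entity."""
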