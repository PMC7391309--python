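"""Exception hierarchy for the isar package."""


class IsarError(Exception):
    """Base class for all package errors."""


class FormatError(IsarError):
    """An input file does not have the expected layout (e.g. missing column)."""


class ValidationError(IsarError):
    """A value violates a domain invariant (negative abundance, area <= 0, ...)."""


class DomainError(IsarError, ValueError):
    """An operation was called outside its mathematical domain."""


class InferenceError(IsarError):
    """A regression or classification cannot be performed on the given inputs."""
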