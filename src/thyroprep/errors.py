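"""Exception hierarchy shared across the pipeline stages."""


class ThyroprepError(Exception):
    """Base class for all package errors."""


class ValidationError(ThyroprepError, ValueError):
    """An input violates a documented precondition or type invariant."""


class ContractError(ThyroprepError, ValueError):
    """A pluggable component (e.g. a feature extractor) broke its contract."""


class TickBarNotFoundError(ThyroprepError):
    """No column in the search region shows periodic tick structure."""


class EmptyImageError(ThyroprepError):
    """The image contains no non-zero pixels to segment."""
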