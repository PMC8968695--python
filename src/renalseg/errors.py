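"""Exception hierarchy.

Everything subclasses :class:`ValueError` so callers that do not care about
the fine distinctions can catch one built-in type.
"""


class RenalsegError(ValueError):
    """Base class for all package-specific errors."""


class ConfigurationError(RenalsegError):
    """A configuration object violates its invariants."""


class DomainError(RenalsegError):
    """An input value lies outside the mathematical domain of an operation."""


class DegenerateInputError(RenalsegError):
    """Input is structurally valid but degenerate (e.g. zero variance)."""


class DivergenceError(RenalsegError):
    """Training produced a non-finite loss."""

    def __init__(self, message, history=None):
        super().__init__(message)
        self.history = history
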