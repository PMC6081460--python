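"""Exception types shared across the toolkit."""


class OncomarkError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(OncomarkError, ValueError):
    """Raised when an argument violates an operation's preconditions."""


class InvalidStateError(OncomarkError, RuntimeError):
    """Raised when an object is not in the state an operation requires."""
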