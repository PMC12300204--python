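"""Exception hierarchy shared across the package."""


class GazeidError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(GazeidError):
    """An input violates a documented precondition or invariant."""


class FormatError(GazeidError):
    """A file does not conform to the expected on-disk layout."""


class InsufficientDataError(GazeidError):
    """Not enough clean data survives filtering to honour the request.

    Carries ``achievable``, the count that could have been satisfied.
    """

    def __init__(self, message: str, achievable: int | None = None):
        super().__init__(message)
        self.achievable = achievable
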