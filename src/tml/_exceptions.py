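"""Exception hierarchy shared across the package.

Every error a caller may reasonably want to catch programmatically has its
own class; all derive from :class:`TMLError` so ``except TMLError`` catches
anything raised deliberately by this package.
"""


class TMLError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(TMLError):
    """Feature columns do not match what a model or collection expects."""


class FormatError(TMLError):
    """A file or serialized artifact is malformed or of the wrong layout."""


class IntegrityError(TMLError):
    """Data violates a uniqueness or consistency invariant."""


class ConfigurationError(TMLError):
    """An option, hyperparameter or config value is invalid."""


class DependencyError(TMLError):
    """A pipeline stage's prerequisite artifact is missing."""


class DimensionError(TMLError):
    """Array shapes are incompatible."""


class FingerprintParseError(FormatError):
    """A fingerprint bitstring contains an illegal character.

    ``position`` is the 1-based index of the first offending character.
    """

    def __init__(self, message: str, position: int):
        super().__init__(message)
        self.position = position
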