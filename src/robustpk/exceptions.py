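"""Exception hierarchy.

Exit-code mapping used by the CLI: DataValidationError -> 3,
NumericalError -> 4, usage errors -> 2 (click's default).
"""


class RobustPKError(Exception):
    """Base class for package errors."""


class PKDomainError(RobustPKError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class DataValidationError(RobustPKError, ValueError):
    """Input data violate a structural or positivity requirement."""


class NumericalError(RobustPKError, RuntimeError):
    """A numerical procedure failed (non-finite posterior, no bracket, ...)."""
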