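"""Exception hierarchy shared across the package."""


class NrltrError(Exception):
    """Base class for all package errors."""


class ParameterError(NrltrError, ValueError):
    """An operation received parameters violating its preconditions."""


class FormatError(NrltrError, ValueError):
    """An on-disk artifact failed validation.

    ``locator`` carries the record ordinal (1-based) or file line where the
    problem was found, when known.
    """

    def __init__(self, message: str, locator: int | None = None):
        self.locator = locator
        if locator is not None:
            message = f"{message} (record {locator})"
        super().__init__(message)


class CoordinateError(NrltrError, ValueError):
    """A genomic coordinate fell outside its sequence."""


class PairingError(NrltrError, ValueError):
    """A read lacked its mate where paired iteration was required."""


class UndefinedDistanceError(NrltrError, ValueError):
    """A pairwise distance could not be computed (no comparable columns)."""
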