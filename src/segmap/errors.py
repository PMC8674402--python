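"""Exception hierarchy shared across the package."""


class SegmapError(Exception):
    """Base class for all package-specific errors."""


class InputError(SegmapError, ValueError):
    """Malformed or out-of-contract input."""


class DomainError(InputError):
    """A numeric argument lies outside its mathematical domain."""


class DegenerateInputError(InputError):
    """Input is valid in form but carries no usable information."""


class UndefinedStatisticError(SegmapError, ZeroDivisionError):
    """The requested statistic is undefined for this input."""


class ConflictError(SegmapError):
    """Interval evidence is mutually contradictory.

    Raised when positive evidence intervals have an empty intersection, or
    when negative evidence erases the whole candidate region.
    """

    def __init__(self, message: str, members=()):
        super().__init__(message)
        self.members = tuple(members)
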