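"""Exception hierarchy shared across the toolkit.

Exit-code mapping used by the CLI: UsageError -> 2, input/format errors -> 3,
ResourceLimitError -> 4.
"""


class BraggkitError(Exception):
    """Base class for all toolkit errors."""


class UsageError(BraggkitError):
    """Bad invocation: unknown command, invalid flag value."""


class InputError(BraggkitError):
    """Invalid input data (bad cell, malformed file, out-of-range value)."""


class InvalidCellError(InputError):
    """Unit-cell parameters do not define a positive-definite metric."""


class FormatError(InputError):
    """A file does not conform to its declared format."""


class UnsupportedSpaceGroupError(InputError):
    """Space-group label not in the built-in operator table."""


class UnknownElementError(InputError):
    """Element symbol with no built-in form-factor coefficients."""


class SpecificationError(InputError):
    """A synthetic-frame specification is internally inconsistent."""


class SaturationError(InputError):
    """Pixel counts exceed the range of the output format."""


class OrderingError(InputError):
    """Timestamps in a stream are not monotone non-decreasing."""

    def __init__(self, index: int, message: str | None = None):
        self.index = index
        super().__init__(message or f"timestamp decreases at record index {index}")


class EmptyComparisonError(InputError):
    """Two reflection sets share no Miller indices."""


class ResourceLimitError(BraggkitError):
    """A configured size/memory cap would be exceeded."""
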