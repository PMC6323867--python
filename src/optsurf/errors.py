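"""Exception taxonomy shared by all modules.

Every error raised by the public API derives from :class:`OptsurfError`, so
callers (and the CLI) can catch one base class.  The subclasses mirror the
failure categories of the pipeline: bad arguments, mode mismatches between a
phantom and an operation, insufficient data for reconstruction or
registration, misaligned inputs, degenerate channels, and file-format
problems.
"""


class OptsurfError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(OptsurfError, ValueError):
    """An argument violates a documented precondition."""


class ModeMismatchError(OptsurfError):
    """The phantom lacks the grid required by the requested projection mode."""


class InsufficientDataError(OptsurfError):
    """Not enough projections (or points) to run the operation."""


class InsufficientLandmarksError(InsufficientDataError):
    """Fewer than three non-collinear landmark pairs."""


class AlignmentRequiredError(OptsurfError):
    """Inputs have mismatched shapes; register/resample them first."""


class DegenerateChannelError(OptsurfError):
    """A channel has no usable background estimate (e.g. zero)."""


class FormatError(OptsurfError, IOError):
    """A file is truncated or uses an unsupported dialect."""
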