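"""Exception hierarchy for psnkit.

All errors raised by the library derive from :class:`PsnkitError` so callers
can catch everything from one place; the CLI maps them to exit code 1 with
a clean message.
"""


class PsnkitError(Exception):
    """Base class for all psnkit errors."""


class EnsembleFormatError(PsnkitError):
    """The input file could not be parsed as a structural ensemble."""


class MalformedEnsembleError(PsnkitError):
    """Frames of the ensemble disagree in atom count or ordering."""


class EmptyInputError(PsnkitError):
    """The input contains no frames (or no atoms)."""


class MassTableError(PsnkitError):
    """A mass table failed validation (non-positive mass, duplicate key)."""


class MassLookupError(PsnkitError):
    """No mass could be resolved for an atom."""


class EmptyNetworkError(PsnkitError):
    """Side-chain selection produced an empty node set."""


class InsufficientFramesError(PsnkitError):
    """Fewer frames than jackknife subsets requested."""


class ScheduleError(PsnkitError):
    """A contact schedule is invalid or has no 3D realization."""
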