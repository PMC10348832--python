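"""Exception hierarchy.

Every error raised on a user-facing contract violation derives from
:class:`MDSieveError`, so callers can catch the package's failures with one
``except`` clause while programming errors (plain ``TypeError`` etc.) still
surface unchanged.
"""


class MDSieveError(Exception):
    """Base class for all mdsieve contract violations."""


class InputError(MDSieveError):
    """An input file is missing, unreadable, or malformed."""


class ConsistencyError(MDSieveError):
    """Two inputs that must agree (e.g. atom counts) do not."""


class SelectionError(MDSieveError):
    """An atom selection failed to parse or matched no atoms."""


class BoundsError(MDSieveError, IndexError):
    """A frame or atom index is out of range."""


class AlignmentError(MDSieveError):
    """An imported per-frame property file does not cover every frame."""


class DegenerateRangeError(MDSieveError):
    """A property series has zero variance; binning needs an explicit range."""


class SampleSizeError(MDSieveError):
    """A requested sample size is impossible for the available frames."""


class BinEdgeMismatchError(MDSieveError):
    """Two histograms being compared were built on different bin edges."""
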