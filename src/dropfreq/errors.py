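"""Exception taxonomy shared across the package.

Each class maps to one CLI exit code (see :mod:`dropfreq.cli`): usage and
parameter problems, I/O and format problems, spectra without a usable peak,
and inputs too short to analyse are distinguishable by type.
"""


class DropfreqError(Exception):
    """Base class for all package errors."""


class ParameterError(DropfreqError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(DropfreqError, IOError):
    """Unreadable/unwritable file or unsupported container."""


class InvariantError(DropfreqError, ValueError):
    """Input data violates a structural invariant (e.g. mixed resolutions)."""


class EmptyInputError(DropfreqError, ValueError):
    """No frames / no data where at least one item is required."""


class ZeroVectorError(DropfreqError, ValueError):
    """All-zero frame: cosine similarity is undefined for zero vectors."""


class DimensionError(DropfreqError, ValueError):
    """Vector length or frame resolution mismatch."""


class AlignmentError(DropfreqError, ValueError):
    """Clips to be composed disagree in frame count or frame rate."""


class NoPeakError(DropfreqError, RuntimeError):
    """No spectral peak satisfies the selection rule."""


class DegenerateSpectrumError(NoPeakError):
    """The similarity vector is constant: no oscillation is present."""


class InsufficientDataError(DropfreqError, RuntimeError):
    """Too few frames/similarities buffered for the requested estimate."""
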