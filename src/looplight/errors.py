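"""Exception types shared across the package.

All errors derive from :class:`LooplightError` (a ``ValueError``) so callers
can catch package-level failures with one handler while standard ``ValueError``
semantics are preserved.
"""


class LooplightError(ValueError):
    """Base class for all looplight errors."""


class InvalidDesignError(LooplightError):
    """An experimental design parameter is unusable (e.g. N < 3 event types,
    repetitions not divisible by the number of runs)."""


class InvalidDimensionError(LooplightError):
    """A dimensionality requirement is violated (e.g. embedding into < 2 voxels)."""


class InvalidSignalError(LooplightError):
    """The signal construction degenerated (e.g. all-zero pattern with psc > 0)."""


class InvalidParameterError(LooplightError):
    """A numeric parameter is outside its valid range."""


class InvalidMaskError(LooplightError):
    """A mask is empty or otherwise unusable."""


class InvalidDurationError(LooplightError):
    """A run is too short to contain its events."""


class InvalidScheduleError(LooplightError):
    """An event falls outside the run it belongs to."""


class SingularDesignError(LooplightError):
    """A design matrix is rank deficient."""


class IncompatibleMapsError(LooplightError):
    """Volumes/maps that must share shape and mask do not."""


class InvalidDistanceError(LooplightError):
    """A distance matrix is asymmetric, non-square or has negative entries."""


class InvalidFiltrationError(LooplightError):
    """A filtration violates the face-before-coface ordering contract."""


class IncompleteAnalysisError(LooplightError):
    """A statistic map is requested but some in-mask voxel has no barcode."""


class InsufficientSampleError(LooplightError):
    """A group test was attempted with fewer than two participants."""
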