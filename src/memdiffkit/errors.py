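"""Exception hierarchy shared across the package."""


class MemdiffError(Exception):
    """Base class for all memdiffkit errors."""


class ParseError(MemdiffError):
    """A file could not be parsed into the particle data model."""


class SelectionError(MemdiffError):
    """A particle selection matched nothing."""


class NoDistinctPeakError(MemdiffError):
    """A density profile has no distinct peak in the search region."""


class InterceptError(MemdiffError):
    """Two density profiles do not cross exactly once in the search region.

    ``candidates`` holds the z locations of all sign changes found (empty if
    the profiles never cross), which is diagnostic for pore-like or disrupted
    membrane states.
    """

    def __init__(self, message, candidates=()):
        super().__init__(message)
        self.candidates = tuple(candidates)


class SpecError(MemdiffError):
    """A synthetic-data specification is internally inconsistent."""


class CalibrationError(MemdiffError):
    """A scintillation calibration cannot be constructed or applied."""


class AnalysisError(MemdiffError):
    """An analysis precondition is violated."""
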