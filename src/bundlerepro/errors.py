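"""Exception hierarchy for bundlerepro."""


class BundleReproError(Exception):
    """Base class for all bundlerepro errors."""


class FormatError(BundleReproError):
    """A tractogram or image file is unreadable, corrupt or unsupported."""


class GridMismatchError(BundleReproError):
    """Two objects that must share a reference grid do not."""


class ParentMismatchError(BundleReproError):
    """Two selections that must index the same parent tractogram do not."""


class ResolutionError(BundleReproError):
    """Bundle streamlines could not be matched back to the parent tractogram."""

    def __init__(self, message: str, n_failed: int = 0):
        super().__init__(message)
        self.n_failed = n_failed


class UniverseError(BundleReproError):
    """A selection/mask contains elements outside the stated universe."""


class UndefinedMeasureError(BundleReproError):
    """A measure is undefined for the given input (e.g. zero variance)."""


class StudyError(BundleReproError):
    """Study-harness bookkeeping failure (missing variants, bad manifest...)."""
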