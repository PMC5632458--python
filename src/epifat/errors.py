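"""Exception hierarchy for the segmentation pipeline."""


class EpifatError(Exception):
    """Base class for all package-specific errors."""


class DegenerateSliceError(EpifatError, ValueError):
    """Raised when a slice has too little luminance structure to process
    (e.g. a constant-valued image for tone mapping or thresholding)."""


class EmptyROIError(EpifatError, RuntimeError):
    """Raised when ROI extraction finds no heart candidate on a slice."""

    def __init__(self, message: str, slice_index: int | None = None):
        super().__init__(message)
        self.slice_index = slice_index


class NoPatchesError(EpifatError, RuntimeError):
    """Raised when the ROI is too small to host a single feature patch."""


class InsufficientDataError(EpifatError, ValueError):
    """Raised when fewer feature points than clusters are available."""


class EmptyClusterError(EpifatError, RuntimeError):
    """Raised when the selected fuzzy cluster carries no weight
    (all-zero membership field), so moments/fitting are undefined."""


class MissingControlsError(EpifatError, ValueError):
    """Raised when no control angles are available for arc interpolation."""


class UndefinedMetricError(EpifatError, ZeroDivisionError):
    """Raised for 0/0 metric cases (e.g. Dice of two empty masks)."""


class InvalidSpecError(EpifatError, ValueError):
    """Raised for geometrically impossible phantom specifications."""


class MetadataError(EpifatError, ValueError):
    """Raised when required image metadata (spacing, thickness) is absent
    or inconsistent across a series."""
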