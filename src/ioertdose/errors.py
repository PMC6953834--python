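"""Exception hierarchy for the IOERT dose-comparison toolkit."""


class IOERTError(Exception):
    """Base class for all toolkit errors."""


class FormatError(IOERTError):
    """File could not be read as a supported image format."""


class DimensionalityError(IOERTError):
    """Image is not a 3D volume."""


class GridMismatchError(IOERTError):
    """Two volumes/masks that must share a grid do not."""


class GeometryError(IOERTError):
    """A geometric construction is invalid (out of bounds, degenerate)."""


class EmptyMaskError(IOERTError):
    """A statistic or metric was requested over an empty mask."""


class SeedError(IOERTError):
    """A region-growing seed violates its preconditions."""


class SegmentationError(IOERTError):
    """Segmentation produced an empty or fragmentary result."""


class InitializationError(IOERTError):
    """Registration initialisation is too far from alignment to proceed."""


class ConvergenceError(IOERTError):
    """The registration optimiser failed to converge."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ConfigError(IOERTError):
    """A configuration value is missing or inconsistent."""


class EmptyAnalysisError(IOERTError):
    """Gamma analysis mask is empty (no voxel above the dose threshold)."""


class SchemaError(IOERTError):
    """A serialised report is missing required fields."""


class IncompleteRimError(GeometryError):
    """The applicator's distal rim covers too few angular bins."""
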