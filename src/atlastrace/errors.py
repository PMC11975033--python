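"""Exception hierarchy for the atlastrace pipeline.

Every stage raises a subclass of :class:`AtlasTraceError`, so callers (and the
CLI) can distinguish pipeline failures from programming errors.
"""


class AtlasTraceError(Exception):
    """Base class for all atlastrace errors."""


class FormatError(AtlasTraceError):
    """A file could not be parsed as the expected format (e.g. non-integer label volume)."""


class AtlasValidationError(AtlasTraceError):
    """Atlas volume and region table are mutually inconsistent."""


class RegionLookupError(AtlasTraceError, KeyError):
    """A region id does not exist in the region table (or is the background id 0)."""


class InsufficientPointsError(AtlasTraceError):
    """Too few control points to fit a transform (minimum 3 pairs)."""


class DegenerateGeometryError(AtlasTraceError):
    """Geometry is degenerate: collinear control points, coplanar boundary cloud, ..."""


class EmptyExtentError(AtlasTraceError):
    """An anterior-posterior slice contains no cortex voxels in the requested hemisphere."""


class MissingTransformError(AtlasTraceError):
    """Cells reference sections for which no fitted transform is available."""


class TopologyError(AtlasTraceError):
    """A mesh that must be closed (watertight) is not."""


class GridMismatchError(AtlasTraceError):
    """Two voxel solids live on different grids (voxel size or frame)."""


class UndefinedDenominatorError(AtlasTraceError):
    """Percent overlap requested against an empty target voxel set."""


class DimensionError(AtlasTraceError):
    """Mask and signal image shapes disagree."""


class MaskValidationError(AtlasTraceError):
    """A region mask contains values other than 0 and 1."""


class NormalizationError(AtlasTraceError):
    """An animal's total signal is zero; innervation fractions are undefined."""


class ConfigurationError(AtlasTraceError):
    """Invalid run configuration (e.g. threshold ordering violated)."""
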