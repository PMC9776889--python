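"""Exception hierarchy shared across the pipeline stages."""


class LvtrackError(Exception):
    """Base class for all package errors."""


class SchemaError(LvtrackError):
    """A sidecar or table is missing a required field."""


class IntegrityError(LvtrackError):
    """Data are internally inconsistent (frame counts, duplicate keys, ...)."""


class GeometryError(LvtrackError):
    """A geometric precondition is violated (pool outside frame, degenerate contour)."""


class NoBorderFound(LvtrackError):
    """Segmentation could not locate a blood-pool border in a frame."""


class SegmentationRejected(LvtrackError):
    """Too many frames of a series failed segmentation."""


class NoCyclesFound(LvtrackError):
    """Cycle detection found no complete cardiac cycle in a trace."""


class PhasePickError(LvtrackError):
    """End-diastole / end-systole phases could not be identified."""


class ClassificationError(LvtrackError):
    """No slice could be classified as basal or apical."""


class AnalysisError(LvtrackError):
    """A derived quantity (correlation, torsion correlation, ...) is undefined."""
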