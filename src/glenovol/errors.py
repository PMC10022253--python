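"""Exception and warning hierarchy for glenovol."""


class GlenovolError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GlenovolError):
    """A file could not be parsed as the expected format."""


class GeometryError(GlenovolError):
    """Invalid spatial input: degenerate landmarks, non-orthonormal axes, ..."""


class LandmarkError(GlenovolError):
    """Fiducial file is missing, or mislabels, a required landmark."""


class ShapeError(GlenovolError):
    """Array arguments have incompatible shapes or lengths."""


class EmptySegmentationError(GlenovolError):
    """Region growing produced no voxels (seed below threshold)."""


class VocabularyError(GlenovolError):
    """A categorical label is outside the accepted vocabulary."""


class ConfigError(GlenovolError):
    """Invalid configuration value for a simulation or pipeline run."""


class DegenerateVarianceError(GlenovolError):
    """A statistic is undefined because an input has zero variance."""


class OrientationWarning(UserWarning):
    """Anatomically implausible pose (e.g. near-horizontal medial border)."""


class PlausibilityWarning(UserWarning):
    """Inputs are consistent but clinically implausible (e.g. frame origin far from mask)."""


class DegenerateSampleWarning(UserWarning):
    """A summary statistic was computed from a degenerate sample (n = 1)."""
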