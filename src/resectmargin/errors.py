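"""Exception hierarchy for the resectmargin pipeline.

Every stage raises a subclass of :class:`ResectMarginError` so the pipeline
driver can abort with a stage name and a machine-readable code.
"""


class ResectMarginError(Exception):
    """Base class for all package errors."""

    code = "error"


class FormatError(ResectMarginError):
    """Unreadable or unrecognized image file."""

    code = "format"


class MetadataError(ResectMarginError):
    """Inconsistent image metadata (e.g. irregular DICOM slice spacing)."""

    code = "metadata"


class ResampleError(ResectMarginError):
    """Degenerate geometry for the requested resampling."""

    code = "resample"


class PreconditionError(ResectMarginError):
    """An operation's documented precondition was violated."""

    code = "precondition"


class GridMismatchError(PreconditionError):
    """Two masks/volumes do not share shape, spacing and origin."""

    code = "grid_mismatch"


class EmptyInputError(PreconditionError):
    """Operation requires a non-empty mask or point set."""

    code = "empty_input"


class SegmentationError(ResectMarginError):
    """Automatic segmentation could not find the expected structure."""

    code = "segmentation"


class SeedError(ResectMarginError):
    """Tumor seed outside the lung or below the tissue HU floor."""

    code = "seed"


class RunawayGrowthError(ResectMarginError):
    """Region growing exceeded the allowed fraction of the lung volume."""

    code = "runaway_growth"


class GeometryError(ResectMarginError):
    """Masks are in geometrically impossible configuration."""

    code = "geometry"


class DegenerateInputError(ResectMarginError):
    """Statistic undefined for the given input (e.g. zero-variance t-test)."""

    code = "degenerate"


class PipelineError(ResectMarginError):
    """A pipeline stage failed in a way that blocks downstream stages."""

    code = "pipeline"


class PhantomSpecError(ResectMarginError):
    """Phantom specification violates its invariants."""

    code = "phantom_spec"


class CountError(ResectMarginError):
    """Requested more items than are available."""

    code = "count"


class ConfigurationError(ResectMarginError):
    """Invalid or incomplete pipeline configuration."""

    code = "configuration"
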