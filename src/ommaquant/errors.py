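"""Exception hierarchy shared across the pipeline stages."""


class OmmaquantError(Exception):
    """Base class for all package-specific failures."""


class ImageFormatError(OmmaquantError, ValueError):
    """Raised for unreadable files or unsupported pixel layouts."""


class DegenerateInputError(OmmaquantError, ValueError):
    """Raised when an image or point set cannot support the requested
    operation (e.g. a constant image has no pixel above its quantile)."""


class GeometryError(OmmaquantError, ValueError):
    """Raised for singular covariances, out-of-frame ellipses and similar
    degenerate geometry."""


class StageError(OmmaquantError, RuntimeError):
    """Wraps a failure inside the segmentation pipeline with a stage label."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
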