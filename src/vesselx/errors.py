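"""Exception hierarchy shared across the pipeline stages."""


class VesselxError(Exception):
    """Base class for all package-specific errors."""


class InputFormatError(VesselxError):
    """Raised for unreadable files or images with unsupported layout."""


class DegenerateInputError(VesselxError):
    """Raised when an input is structurally valid but unusable
    (empty field of view, kernel larger than the image, ...)."""


class ConsistencyError(VesselxError):
    """Raised when two artifacts that must agree (dimensions, metadata)
    do not."""


class PipelineStageError(VesselxError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original}")
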