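"""Exception hierarchy shared across the pipeline."""


class QuantError(Exception):
    """Base class for all package-specific errors."""


class VolumeFormatError(QuantError):
    """A file could not be read or violates the format contract."""


class DegenerateInputError(QuantError):
    """Input is structurally valid but carries no usable signal
    (all-zero region, empty mask, ...)."""


class SegmentationError(QuantError):
    """The active surface produced no usable lesion mask."""


class ConfigurationError(QuantError):
    """Mutually inconsistent or incomplete configuration."""


class PhantomSpecError(QuantError):
    """A phantom specification violates its geometric invariants."""


class PipelineStageError(QuantError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
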