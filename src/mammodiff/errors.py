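"""Exception hierarchy for the mammodiff pipeline.

Stage-specific errors subclass ValueError / OSError so callers can catch
either the specific pipeline failure or the generic Python category.
"""


class MammodiffError(Exception):
    """Base class for all pipeline-specific errors."""


class MetadataError(MammodiffError, ValueError):
    """View/laterality metadata could not be determined for an image."""


class SegmentationError(MammodiffError, ValueError):
    """Breast segmentation produced an empty mask.

    Carries the threshold that was applied so the caller can decide on a
    per-file override.
    """

    def __init__(self, message: str, threshold: int | None = None):
        super().__init__(message)
        self.threshold = threshold


class DegenerateROIError(MammodiffError, ValueError):
    """A region of interest is too small for the requested computation."""
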