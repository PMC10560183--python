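"""Exception types raised across the pipeline.

Each stage signals its own failure mode so that the cohort runner can
attribute a failed clip to ingestion, region selection, trimming, shape
analysis or model fitting and continue with the remaining cases.
"""


class Face4DError(Exception):
    """Base class for all package errors."""


class MeshFormatError(Face4DError):
    """A mesh file could not be read or violates the expected format."""


class CorrespondenceError(Face4DError):
    """Frames of a sequence do not share a common vertex count/order."""


class LandmarkError(Face4DError):
    """A landmark map is missing required names or has invalid indices."""


class ROIError(Face4DError):
    """A region-of-interest selection is empty or invalid."""


class TrimError(Face4DError):
    """No expression could be detected when trimming a sequence."""


class DegenerateConfigurationError(Face4DError):
    """A landmark configuration is too degenerate to superimpose."""


class FitError(Face4DError):
    """A statistical model could not be fitted on the given data."""
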