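"""Exception hierarchy for the cvtspect pipeline.

Every stage raises a subclass of :class:`CvtSpectError` so that the design
grid driver can catch failures per design and keep going.
"""


class CvtSpectError(Exception):
    """Base class for all cvtspect errors."""


class ConfigurationError(CvtSpectError):
    """Invalid or inconsistent configuration (geometry, filter, grid...)."""


class ConsistencyError(CvtSpectError):
    """Two inputs that must agree (grids, masks, binnings) do not."""


class PlacementError(CvtSpectError):
    """Lesion placement could not reach the target volume fraction."""

    def __init__(self, message: str, achieved_fraction: float):
        super().__init__(message)
        self.achieved_fraction = achieved_fraction


class NormalisationError(CvtSpectError):
    """Projection count normalisation is impossible (e.g. all-zero input)."""


class ReconstructionError(CvtSpectError):
    """Iterative reconstruction produced NaN or otherwise failed."""


class SegmentationError(CvtSpectError):
    """Lung segmentation produced an empty or degenerate mask."""


class AnalysisError(CvtSpectError):
    """CV analysis could not be carried out (no qualifying kernels...)."""
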