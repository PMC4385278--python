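"""Analysis-volume definition from the reconstructed healthy distribution.

The whole-lung mask takes voxels above half the (robust) maximum lung
value in the mean healthy reconstruction, keeping the two largest
connected components.  The reduced-lung mask erodes that boundary by one
voxel, discarding the edge layer whose steep activity gradient inflates
CV values irrespective of disease.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import SegmentationError
from .recon import ReconstructedImage


@dataclass
class AnalysisMask:
    values: np.ndarray  # boolean
    kind: str  # "whole" | "reduced"
    source: dict = field(default_factory=dict)

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())


def segment_lung(mean_healthy_image: ReconstructedImage,
                 robust_percentile: float = 99.5,
                 n_components: int = 2) -> AnalysisMask:
    """Threshold at half the robust maximum; keep the largest components.

    The robust maximum is the ``robust_percentile`` of the image so a few
    hot noise voxels cannot shift the threshold.  Doubling the image
    intensity leaves the mask unchanged (the threshold is relative).
    """
    vals = np.asarray(mean_healthy_image.values, dtype=np.float64)
    if not np.any(vals > 0):
        raise SegmentationError("image contains no positive values")
    vmax = np.percentile(vals[vals > 0], robust_percentile)
    mask = vals > 0.5 * vmax
    if not mask.any():
        raise SegmentationError("half-maximum threshold produced an empty mask")
    labels, n = ndimage.label(mask)
    if n > n_components:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        keep = np.argsort(sizes)[-n_components:] + 1
        mask = np.isin(labels, keep)
    return AnalysisMask(
        values=mask, kind="whole",
        source={"threshold": float(0.5 * vmax), "robust_max": float(vmax),
                **mean_healthy_image.provenance},
    )


def erode_mask(mask: AnalysisMask) -> AnalysisMask:
    """One-voxel erosion (3x3x3 structuring element) -> the reduced lung."""
    struct = np.ones((3, 3, 3), dtype=bool)
    eroded = ndimage.binary_erosion(mask.values, structure=struct, border_value=0)
    if not eroded.any():
        raise SegmentationError("erosion removed the entire mask")
    removed = 1.0 - eroded.sum() / mask.values.sum()
    return AnalysisMask(
        values=eroded, kind="reduced",
        source={**mask.source, "fraction_removed_by_erosion": float(removed)},
    )
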