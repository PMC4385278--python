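"""Butterworth low-pass post-filtering of reconstructed volumes.

The filter gain at radial spatial frequency f (cycles/cm) is

    A(f) = [1 + (|f| / Q)^p]^(-1/2)

with cutoff Q (A(Q) = 2^-1/2) and power factor p controlling the roll-off.
Filtering is applied in the 3-D Fourier domain without padding (circular
convolution); the lungs sit well inside the volume so wrap-around is
negligible.  Negative ripple values are clipped to zero, mirroring the
physical non-negativity of activity, before any CV analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft

from .errors import ConfigurationError
from .recon import ReconstructedImage


@dataclass(frozen=True)
class FilterSpec:
    """Cutoff in cycles/cm; ``cutoff_cm=None`` means no filtering."""

    cutoff_cm: float | None
    power: int = 6

    def __post_init__(self):
        if self.cutoff_cm is not None and self.cutoff_cm <= 0:
            raise ConfigurationError("cutoff frequency must be positive")
        if self.power < 1:
            raise ConfigurationError("power factor must be >= 1")

    @property
    def is_identity(self) -> bool:
        return self.cutoff_cm is None

    @property
    def label(self) -> str:
        return "none" if self.is_identity else f"{self.cutoff_cm:g}"


def butterworth_amplitude(f, spec: FilterSpec):
    """Filter gain at spatial frequency ``f`` (cycles/cm); identity spec -> 1."""
    f = np.abs(np.asarray(f, dtype=np.float64))
    if spec.is_identity:
        return np.ones_like(f)
    return (1.0 + (f / spec.cutoff_cm) ** spec.power) ** -0.5


def apply_filter(image: ReconstructedImage, spec: FilterSpec,
                 clip_negative: bool = False) -> ReconstructedImage:
    """3-D Butterworth filtering; the mean (DC) value is preserved.

    ``clip_negative=True`` zeroes the small negative ripples (done by the
    pipeline just before CV analysis; note it perturbs the mean slightly).
    """
    if spec.is_identity:
        return image.copy_with(image.values.copy(), cutoff="none")
    vox = image.voxel_size_cm
    nyquist = 1.0 / (2.0 * vox)
    if spec.cutoff_cm > nyquist + 1e-12:
        raise ConfigurationError(
            f"cutoff {spec.cutoff_cm} cycles/cm exceeds Nyquist {nyquist:.3f}"
        )
    vals = np.asarray(image.values, dtype=np.float64)
    freqs = [sfft.fftfreq(n, d=vox) for n in vals.shape[:2]]
    fr = sfft.rfftfreq(vals.shape[2], d=vox)
    f2 = (freqs[0][:, None, None] ** 2 + freqs[1][None, :, None] ** 2
          + fr[None, None, :] ** 2)
    gain = butterworth_amplitude(np.sqrt(f2), spec)
    out = sfft.irfftn(sfft.rfftn(vals) * gain, s=vals.shape)
    if clip_negative:
        np.clip(out, 0.0, None, out=out)
    return image.copy_with(out, cutoff=spec.label)
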