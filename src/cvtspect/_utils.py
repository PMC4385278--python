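"""Small shared helpers: deterministic seed derivation and grid resampling."""

from __future__ import annotations

import zlib

import numpy as np
from scipy import ndimage

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def derive_seed(base_seed: int, *keys) -> np.random.SeedSequence:
    """Derive an independent seed stream from a base seed and a key path.

    String keys are hashed with CRC32 so that e.g. (base, "LEHR", 125, 7)
    always maps to the same stream, independent of Python's randomised
    ``hash()``.  Used so every (design, realisation) pair is reproducible
    in isolation.
    """
    ints = []
    for k in keys:
        if isinstance(k, str):
            ints.append(zlib.crc32(k.encode("utf-8")))
        elif isinstance(k, (int, np.integer)):
            ints.append(int(k) & 0xFFFFFFFF)
        elif isinstance(k, float):
            ints.append(zlib.crc32(repr(k).encode("utf-8")))
        else:
            raise TypeError(f"unsupported seed key type: {type(k)!r}")
    return np.random.SeedSequence(entropy=int(base_seed) & 0x7FFFFFFF, spawn_key=tuple(ints))


def rng_for(base_seed: int, *keys) -> np.random.Generator:
    return np.random.default_rng(derive_seed(base_seed, *keys))


def resample_volume(values: np.ndarray, src_voxel_cm: float, dst_shape, dst_voxel_cm: float) -> np.ndarray:
    """Resample a 3-D volume onto a new isotropic grid with a shared centre.

    Block-averages when the destination voxel is an integer multiple of the
    source voxel and shapes match exactly; otherwise uses linear
    interpolation via ``scipy.ndimage.zoom`` followed by centre crop/pad.
    """
    values = np.asarray(values, dtype=np.float64)
    factor = dst_voxel_cm / src_voxel_cm
    if abs(factor - round(factor)) < 1e-9 and round(factor) >= 1:
        f = int(round(factor))
        if all(s == d * f for s, d in zip(values.shape, dst_shape)):
            n0, n1, n2 = dst_shape
            return values.reshape(n0, f, n1, f, n2, f).mean(axis=(1, 3, 5))
    zoomed = ndimage.zoom(values, 1.0 / factor, order=1)
    return _center_fit(zoomed, dst_shape)


def _center_fit(arr: np.ndarray, shape) -> np.ndarray:
    out = np.zeros(shape, dtype=arr.dtype)
    src_slices, dst_slices = [], []
    for s, d in zip(arr.shape, shape):
        if s >= d:
            start = (s - d) // 2
            src_slices.append(slice(start, start + d))
            dst_slices.append(slice(0, d))
        else:
            start = (d - s) // 2
            src_slices.append(slice(0, s))
            dst_slices.append(slice(start, start + s))
    out[tuple(dst_slices)] = arr[tuple(src_slices)]
    return out
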