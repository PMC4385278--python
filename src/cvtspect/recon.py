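"""OSEM reconstruction with attenuation and collimator-response compensation.

Standard multiplicative EM update per ordered subset:

    image <- image * backproject_s(measured_s / forward_s(image)) / backproject_s(1)

using the same attenuated, PSF-bearing system model as the forward
simulation.  Subsets take interleaved angles and are visited in
bit-reversed order; with one subset the algorithm is plain MLEM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ConsistencyError, ReconstructionError
from .phantom import AttenuationMap
from .projector import AcquisitionGeometry, CollimatorModel, ProjectionSet, SystemModel


@dataclass(frozen=True)
class ReconConfig:
    n_subsets: int = 16
    n_iterations: int = 4
    attenuation_correction: bool = True
    cdr_correction: bool = True
    voxel_size_cm: float = 0.33

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be >= 1")
        if self.n_subsets < 1:
            raise ConfigurationError("n_subsets must be >= 1")

    @property
    def n_updates(self) -> int:
        return self.n_iterations * self.n_subsets


@dataclass
class ReconstructedImage:
    values: np.ndarray
    voxel_size_cm: float
    provenance: dict = field(default_factory=dict)

    def copy_with(self, values: np.ndarray, **extra) -> "ReconstructedImage":
        return ReconstructedImage(values=values, voxel_size_cm=self.voxel_size_cm,
                                  provenance={**self.provenance, **extra})


def _bit_reversed(n: int) -> list[int]:
    bits = max(1, (n - 1).bit_length())
    order = [int(format(i, f"0{bits}b")[::-1], 2) for i in range(1 << bits)]
    return [i for i in order if i < n]


def _subset_angles(n_angles: int, n_subsets: int) -> list[np.ndarray]:
    if n_angles % n_subsets != 0:
        raise ConfigurationError(f"{n_subsets} subsets do not divide {n_angles} angles")
    return [np.arange(s, n_angles, n_subsets) for s in range(n_subsets)]


def _fov_mask(shape, voxel: float) -> np.ndarray:
    n0, n1 = shape[0], shape[1]
    x = np.arange(n0) - (n0 - 1) / 2.0
    y = np.arange(n1) - (n1 - 1) / 2.0
    r = min(n0, n1) / 2.0
    return ((x[:, None] ** 2 + y[None, :] ** 2) <= r**2)[:, :, None] & np.ones(shape, bool)


class OsemReconstructor:
    """Reusable OSEM engine; build once per (mu, geometry, collimator, config).

    ``snapshots_at`` in :meth:`reconstruct` yields intermediate images at
    the requested iteration numbers, so a single pass over the maximum
    iteration count serves a whole grid of update-count designs.
    """

    def __init__(self, mu: AttenuationMap, geometry: AcquisitionGeometry,
                 collimator: CollimatorModel | str, config: ReconConfig,
                 system: SystemModel | None = None):
        self.config = config
        self.geometry = geometry
        if system is None:
            system = SystemModel(
                mu, geometry, collimator,
                model_psf=config.cdr_correction,
                model_attenuation=config.attenuation_correction,
            )
        self.system = system
        self.subsets = _subset_angles(geometry.n_angles, config.n_subsets)
        self.subset_order = _bit_reversed(config.n_subsets)
        self.fov = _fov_mask(system.shape, system.voxel)
        ones = np.ones((len(self.subsets[0]), *geometry.detector_shape))
        self.sensitivity = [self.system.backward(ones, idx) for idx in self.subsets]
        self._sens_mask = [s > 1e-6 * s.max() for s in self.sensitivity]

    def reconstruct(self, noisy: ProjectionSet, n_iterations: int | None = None,
                    snapshots_at: tuple[int, ...] = ()) -> "ReconstructedImage | dict":
        """Run OSEM; returns the final image, or {iteration: image} if
        ``snapshots_at`` is given."""
        cfg = self.config
        n_iter = cfg.n_iterations if n_iterations is None else n_iterations
        if noisy.counts.shape[0] != self.geometry.n_angles:
            raise ConsistencyError("projection count does not match geometry")
        measured = np.asarray(noisy.counts, dtype=np.float64)
        if np.any(measured < 0):
            raise ReconstructionError("negative measured counts")

        image = np.where(self.fov, 1.0, 0.0)
        snaps: dict[int, ReconstructedImage] = {}
        for it in range(1, n_iter + 1):
            for s in self.subset_order:
                idx = self.subsets[s]
                est = self.system.forward(image, idx)
                ratio = np.zeros_like(est)
                np.divide(measured[idx], est, out=ratio, where=est > 1e-12 * max(est.max(), 1e-300))
                corr = self.system.backward(ratio, idx)
                upd = np.ones_like(image)
                np.divide(corr, self.sensitivity[s], out=upd, where=self._sens_mask[s])
                image *= upd
                if np.any(~np.isfinite(image)):
                    raise ReconstructionError(f"non-finite image at iteration {it}, subset {s}")
            if it in snapshots_at:
                snaps[it] = self._wrap(image.copy(), noisy, it)
        if snapshots_at:
            if n_iter in snapshots_at:
                return snaps
            snaps[n_iter] = self._wrap(image, noisy, n_iter)
            return snaps
        return self._wrap(image, noisy, n_iter)

    def _wrap(self, values: np.ndarray, noisy: ProjectionSet, n_iter: int) -> ReconstructedImage:
        return ReconstructedImage(
            values=values, voxel_size_cm=self.system.voxel,
            provenance={
                "collimator": noisy.collimator,
                "n_iterations": n_iter,
                "n_subsets": self.config.n_subsets,
                "n_updates": n_iter * self.config.n_subsets,
            },
        )


def osem_reconstruct(noisy: ProjectionSet, mu: AttenuationMap,
                     geometry: AcquisitionGeometry, collimator: CollimatorModel | str,
                     config: ReconConfig) -> ReconstructedImage:
    """One-shot OSEM reconstruction (builds the system model internally)."""
    return OsemReconstructor(mu, geometry, collimator, config).reconstruct(noisy)


def poisson_log_likelihood(image: np.ndarray, measured: np.ndarray,
                           system: SystemModel) -> float:
    """Poisson log-likelihood sum(y*log(yhat) - yhat), constants dropped."""
    est = system.forward(image)
    ll = -est.sum()
    pos = measured > 0
    ll += float(np.sum(measured[pos] * np.log(np.maximum(est[pos], 1e-300))))
    return float(ll)


def count_consistency(image: ReconstructedImage, noisy: ProjectionSet,
                      system: SystemModel) -> float:
    """Relative global count mismatch between reprojected image and data."""
    total = noisy.counts.sum()
    if total <= 0:
        raise ConsistencyError("measured data has no counts")
    return float(abs(system.forward(image.values).sum() - total) / total)
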