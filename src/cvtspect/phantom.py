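"""Synthetic thorax phantom for lung SPECT simulation.

Builds a voxelised body containing two lung-shaped regions, a homogeneous
("healthy") tracer distribution, a mild-COPD distribution in which small
spherical lesions of reduced uptake are scattered evenly through the lung,
a piecewise-constant attenuation map, and an optional anisotropic Gaussian
blur standing in for respiratory/cardiac motion averaging.

The lung shape is deliberately simple — two ellipsoids flattened medially
inside an elliptical-cylinder body — because the downstream heterogeneity
analysis depends on lung volume, edge gradients and lesion statistics, not
on anatomical detail.  The lung semi-axes are calibrated at build time so
the voxelised volume matches the configured target (4.2 l at full scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from ._utils import FWHM_TO_SIGMA
from .errors import ConfigurationError, ConsistencyError, PlacementError

#: Linear attenuation coefficients at 140 keV, cm^-1.
DEFAULT_TISSUE_MU = {"air": 0.0, "soft_tissue": 0.15, "lung": 0.04}


@dataclass(frozen=True)
class LungGeometry:
    """Analytic geometry of the body and the two lungs, all lengths in cm.

    Each lung is an ellipsoid centred at ``(+/-lung_center_x, lung_center_y,
    lung_center_z)`` with semi-axes ``lung_semi_axes``, cut by the medial
    plane ``|x| >= medial_gap_cm / 2`` and clipped to the body.  The
    semi-axes are rescaled at voxelisation time so the total voxel volume
    hits ``target_volume_l``.
    """

    body_semi_axes_cm: tuple[float, float] = (16.0, 11.0)
    body_half_height_cm: float = 19.0
    lung_center_x_cm: float = 6.2
    lung_center_y_cm: float = 0.0
    lung_center_z_cm: float = 0.0
    lung_semi_axes_cm: tuple[float, float, float] = (5.3, 8.0, 11.0)
    medial_gap_cm: float = 2.5
    target_volume_l: float = 4.2

    def scaled(self, s: float) -> "LungGeometry":
        """Uniform linear scaling; the volume target scales with s**3."""
        return LungGeometry(
            body_semi_axes_cm=(self.body_semi_axes_cm[0] * s, self.body_semi_axes_cm[1] * s),
            body_half_height_cm=self.body_half_height_cm * s,
            lung_center_x_cm=self.lung_center_x_cm * s,
            lung_center_y_cm=self.lung_center_y_cm * s,
            lung_center_z_cm=self.lung_center_z_cm * s,
            lung_semi_axes_cm=tuple(a * s for a in self.lung_semi_axes_cm),
            medial_gap_cm=self.medial_gap_cm * s,
            target_volume_l=self.target_volume_l * s**3,
        )


@dataclass(frozen=True)
class PhantomSpec:
    """Complete configuration of the voxel phantom."""

    grid_shape: tuple[int, int, int] = (128, 128, 128)
    voxel_size_cm: float = 0.33
    lung_geometry: LungGeometry = field(default_factory=LungGeometry)
    lesion_diameter_cm: float = 1.0
    lesion_concentration_fraction: float = 0.5
    lesion_volume_fraction: float = 0.10
    tissue_mu: dict = field(default_factory=lambda: dict(DEFAULT_TISSUE_MU))
    #: (x, y, z) FWHM of the motion blur; z is craniocaudal.
    motion_blur_fwhm_cm: tuple[float, float, float] = (0.3, 0.3, 1.0)
    seed: int = 0

    def __post_init__(self):
        if self.voxel_size_cm <= 0:
            raise ConfigurationError("voxel_size_cm must be positive")
        if not (0.0 <= self.lesion_concentration_fraction <= 1.0):
            raise ConfigurationError("lesion_concentration_fraction must lie in [0, 1]")
        if not (0.0 <= self.lesion_volume_fraction < 1.0):
            raise ConfigurationError("lesion_volume_fraction must lie in [0, 1)")
        if self.lesion_diameter_cm < self.voxel_size_cm:
            raise ConfigurationError("lesion_diameter_cm must be at least one voxel")
        if any(f < 0 for f in self.motion_blur_fwhm_cm):
            raise ConfigurationError("motion blur FWHM must be non-negative")

    def with_scale(self, s: float) -> "PhantomSpec":
        return replace(self, lung_geometry=self.lung_geometry.scaled(s))


@dataclass
class ActivityMap:
    """Relative activity concentration per voxel (arbitrary units >= 0)."""

    values: np.ndarray
    voxel_size_cm: float

    def total(self) -> float:
        return float(self.values.sum())


@dataclass
class AttenuationMap:
    """Linear attenuation coefficient per voxel, cm^-1."""

    values: np.ndarray
    voxel_size_cm: float


@dataclass
class LungMask:
    values: np.ndarray  # boolean
    voxel_size_cm: float

    @property
    def volume_litres(self) -> float:
        return float(self.values.sum()) * self.voxel_size_cm**3 / 1000.0


def _axis_coords(n: int, voxel: float) -> np.ndarray:
    return (np.arange(n) - (n - 1) / 2.0) * voxel


def grid_coords(spec: PhantomSpec):
    """Sparse (x, y, z) coordinate grids in cm, origin at the grid centre."""
    nx, ny, nz = spec.grid_shape
    v = spec.voxel_size_cm
    return np.meshgrid(
        _axis_coords(nx, v), _axis_coords(ny, v), _axis_coords(nz, v),
        indexing="ij", sparse=True,
    )


def body_mask(spec: PhantomSpec) -> np.ndarray:
    g = spec.lung_geometry
    x, y, z = grid_coords(spec)
    ax, ay = g.body_semi_axes_cm
    return ((x / ax) ** 2 + (y / ay) ** 2 <= 1.0) & (np.abs(z) <= g.body_half_height_cm)


def _lung_voxels(spec: PhantomSpec, scale: float) -> np.ndarray:
    """Boolean mask of both lungs with semi-axes scaled by ``scale``."""
    g = spec.lung_geometry
    x, y, z = grid_coords(spec)
    a, b, c = (s * scale for s in g.lung_semi_axes_cm)
    half_gap = g.medial_gap_cm / 2.0
    dy = ((y - g.lung_center_y_cm) / b) ** 2
    dz = ((z - g.lung_center_z_cm) / c) ** 2
    right = (((x - g.lung_center_x_cm) / a) ** 2 + dy + dz <= 1.0) & (x >= half_gap)
    left = (((x + g.lung_center_x_cm) / a) ** 2 + dy + dz <= 1.0) & (x <= -half_gap)
    return (right | left) & body_mask(spec)


def build_lung_mask(spec: PhantomSpec) -> LungMask:
    """Voxelise the two-lung mask, calibrating semi-axes to the volume target.

    Raises :class:`ConfigurationError` if the configured geometry is
    degenerate or does not fit inside the grid.
    """
    g = spec.lung_geometry
    if min(g.lung_semi_axes_cm) <= 0 or min(g.body_semi_axes_cm) <= 0:
        raise ConfigurationError("lung/body semi-axes must be positive")
    fov_half = np.array(spec.grid_shape) * spec.voxel_size_cm / 2.0
    extent = (
        g.lung_center_x_cm + g.lung_semi_axes_cm[0],
        abs(g.lung_center_y_cm) + g.lung_semi_axes_cm[1],
        abs(g.lung_center_z_cm) + g.lung_semi_axes_cm[2],
    )
    if any(e > f for e, f in zip(extent, fov_half)):
        raise ConfigurationError(
            f"lung geometry (extent {extent}) exceeds grid half-FOV {tuple(fov_half)}"
        )

    target_vox = g.target_volume_l * 1000.0 / spec.voxel_size_cm**3

    def count(s: float) -> float:
        return float(_lung_voxels(spec, s).sum())

    # bracket the volume target with a linear scale factor, then bisect
    lo, hi = 0.5, 1.0
    max_scale = min(f / e for e, f in zip(extent, fov_half))
    while count(hi) < target_vox:
        hi = min(hi * 1.1, max_scale)
        if hi >= max_scale and count(hi) < target_vox:
            raise ConfigurationError("volume target unreachable within the grid")
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        if count(mid) < target_vox:
            lo = mid
        else:
            hi = mid
    mask = _lung_voxels(spec, hi)
    vol = mask.sum() * spec.voxel_size_cm**3 / 1000.0
    if not mask.any() or abs(vol - g.target_volume_l) / g.target_volume_l > 0.05:
        raise ConfigurationError(
            f"calibrated lung volume {vol:.3f} l misses target {g.target_volume_l:.3f} l"
        )
    return LungMask(values=mask, voxel_size_cm=spec.voxel_size_cm)


def _sphere_offsets(diameter_cm: float, voxel_cm: float) -> np.ndarray:
    """Voxel index offsets whose centres lie within the sphere radius."""
    r = diameter_cm / 2.0
    m = int(np.ceil(r / voxel_cm))
    rng_idx = np.arange(-m, m + 1)
    ii, jj, kk = np.meshgrid(rng_idx, rng_idx, rng_idx, indexing="ij")
    inside = (ii**2 + jj**2 + kk**2) * voxel_cm**2 <= r**2 + 1e-12
    return np.stack([ii[inside], jj[inside], kk[inside]], axis=1)


def place_lesions(mask: LungMask, spec: PhantomSpec, seed: int | None = None) -> np.ndarray:
    """Scatter non-overlapping spherical lesions quasi-uniformly over the lung.

    Sphere centres are drawn by rejection sampling from the lung voxels,
    with a minimum centre-to-centre distance of one lesion diameter and the
    whole sphere required to lie inside the lung mask.  Placement stops the
    first time the achieved volume fraction reaches the target; with 1-cm
    spheres the overshoot is a small fraction of a percentage point.

    Returns a boolean lesion mask.  Deterministic given ``seed``.
    """
    if seed is None:
        seed = spec.seed
    target = spec.lesion_volume_fraction
    lesions = np.zeros_like(mask.values)
    if target == 0.0:
        return lesions

    offsets = _sphere_offsets(spec.lesion_diameter_cm, spec.voxel_size_cm)
    # centres from which the full sphere stays inside the lung
    struct = np.zeros(offsets.max(axis=0) - offsets.min(axis=0) + 1, dtype=bool)
    struct[tuple((offsets - offsets.min(axis=0)).T)] = True
    valid = ndimage.binary_erosion(mask.values, structure=struct, border_value=0)
    valid_idx = np.argwhere(valid)
    if valid_idx.size == 0:
        raise PlacementError("no lung voxel can host a full lesion sphere", 0.0)

    lung_vox = int(mask.values.sum())
    sphere_vox = offsets.shape[0]
    rng = np.random.default_rng(seed)
    min_d2 = (spec.lesion_diameter_cm / mask.voxel_size_cm) ** 2  # voxel units
    centres: list[np.ndarray] = []
    placed_vox = 0
    needed = target * lung_vox
    max_attempts = int(200 * needed / sphere_vox) + 1000
    attempts = 0
    while placed_vox < needed and attempts < max_attempts:
        attempts += 1
        c = valid_idx[rng.integers(len(valid_idx))]
        if centres:
            d2 = np.sum((np.asarray(centres) - c) ** 2, axis=1)
            if d2.min() < min_d2:
                continue
        vox = c + offsets
        lesions[vox[:, 0], vox[:, 1], vox[:, 2]] = True
        centres.append(c)
        placed_vox += sphere_vox

    achieved = placed_vox / lung_vox
    if abs(achieved - target) > 0.005:
        raise PlacementError(
            f"reached lesion volume fraction {achieved:.4f} (target {target:.4f}) "
            f"after {attempts} attempts",
            achieved,
        )
    return lesions


def build_activity(mask: LungMask, lesion_mask: np.ndarray | None, spec: PhantomSpec) -> ActivityMap:
    """Activity map: lung tissue at concentration 1, lesions reduced, body cold."""
    values = np.zeros(mask.values.shape, dtype=np.float64)
    values[mask.values] = 1.0
    if lesion_mask is not None and lesion_mask.any():
        if np.any(lesion_mask & ~mask.values):
            raise ConsistencyError("lesion voxels fall outside the lung mask")
        values[lesion_mask] = spec.lesion_concentration_fraction
    return ActivityMap(values=values, voxel_size_cm=mask.voxel_size_cm)


def build_attenuation(spec: PhantomSpec, mask: LungMask) -> AttenuationMap:
    """Piecewise-constant attenuation: air outside the body, soft tissue
    inside, lung mu in the lungs.  Lesions keep lung mu (airway obstruction
    removes tracer, not tissue density)."""
    for label in ("air", "soft_tissue", "lung"):
        if label not in spec.tissue_mu:
            raise ConfigurationError(f"tissue_mu missing label {label!r}")
    mu = np.full(spec.grid_shape, spec.tissue_mu["air"], dtype=np.float64)
    mu[body_mask(spec)] = spec.tissue_mu["soft_tissue"]
    mu[mask.values] = spec.tissue_mu["lung"]
    return AttenuationMap(values=mu, voxel_size_cm=spec.voxel_size_cm)


def apply_motion_blur(activity: ActivityMap, spec: PhantomSpec) -> ActivityMap:
    """Anisotropic Gaussian blur emulating respiratory/cardiac motion averaging."""
    fwhm = spec.motion_blur_fwhm_cm
    if any(f < 0 for f in fwhm):
        raise ConfigurationError("motion blur FWHM must be non-negative")
    if all(f == 0 for f in fwhm):
        return ActivityMap(values=activity.values.copy(), voxel_size_cm=activity.voxel_size_cm)
    sigma = [f * FWHM_TO_SIGMA / activity.voxel_size_cm for f in fwhm]
    blurred = ndimage.gaussian_filter(activity.values, sigma=sigma, mode="constant")
    return ActivityMap(values=blurred, voxel_size_cm=activity.voxel_size_cm)


def build_phantom(spec: PhantomSpec, diseased: bool, seed: int | None = None):
    """Convenience: (lung mask, lesion mask, activity, attenuation).

    ``diseased=False`` gives the homogeneous healthy distribution;
    ``diseased=True`` adds the reduced-uptake lesions.
    """
    mask = build_lung_mask(spec)
    lesions = place_lesions(mask, spec, seed=seed) if diseased else np.zeros_like(mask.values)
    activity = build_activity(mask, lesions, spec)
    mu = build_attenuation(spec, mask)
    return mask, lesions, activity, mu
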