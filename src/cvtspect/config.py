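"""Experiment presets and YAML configuration loading.

Three scales are provided:

* ``full_scale``   — the clinical dimensions: 256^3 phantom at 0.165 cm,
  128 angles, 128^2 detector at 0.33 cm, 16 subsets, 40 realisations.
* ``desk_scale``   — phantom on the reconstruction grid (128^3 at 0.33 cm),
  full anatomy; suitable for single-design studies on a workstation.
* ``mini_scale``   — half-size anatomy on a 64^3 grid, 64 angles, 8
  realisations; runs a small design grid in minutes and is the scale used
  by the test-suite's end-to-end checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .phantom import LungGeometry, PhantomSpec
from .projector import AcquisitionGeometry, build_orbit


@dataclass(frozen=True)
class ExperimentConfig:
    phantom: PhantomSpec
    geometry: AcquisitionGeometry
    n_subsets: int = 16
    n_realisations: int = 40
    n_distance_bins: int = 8
    base_seed: int = 0
    scale_counts: bool = False  # scale clinical count totals by detector-area ratio

    def count_scale(self) -> float:
        if not self.scale_counts:
            return 1.0
        nu, nv = self.geometry.detector_shape
        ref_area = (128 * 0.33) ** 2
        return (nu * self.geometry.detector_bin_cm) * (nv * self.geometry.detector_bin_cm) / ref_area


def _geometry(n: int, n_angles: int, r_min: float = 17.0, r_max: float = 25.0) -> AcquisitionGeometry:
    return AcquisitionGeometry(
        n_angles=n_angles, detector_shape=(n, n), detector_bin_cm=0.33,
        orbit_radii_cm=tuple(build_orbit(n_angles, r_min, r_max)),
    )


def full_scale(base_seed: int = 0) -> ExperimentConfig:
    spec = PhantomSpec(grid_shape=(256, 256, 256), voxel_size_cm=0.165)
    return ExperimentConfig(phantom=spec, geometry=_geometry(128, 128),
                            n_subsets=16, n_realisations=40, base_seed=base_seed)


def desk_scale(base_seed: int = 0) -> ExperimentConfig:
    spec = PhantomSpec(grid_shape=(128, 128, 128), voxel_size_cm=0.33)
    return ExperimentConfig(phantom=spec, geometry=_geometry(128, 128),
                            n_subsets=16, n_realisations=40, base_seed=base_seed)


def mini_scale(base_seed: int = 0, n_realisations: int = 8) -> ExperimentConfig:
    spec = PhantomSpec(grid_shape=(64, 64, 64), voxel_size_cm=0.33,
                       lung_geometry=LungGeometry().scaled(0.5))
    return ExperimentConfig(phantom=spec, geometry=_geometry(64, 64),
                            n_subsets=16, n_realisations=n_realisations,
                            base_seed=base_seed)


PRESETS = {"full_scale": full_scale, "desk_scale": desk_scale, "mini_scale": mini_scale}


def load_config(path) -> ExperimentConfig:
    """Build an ExperimentConfig from a YAML file.

    The file selects a preset and may override scalar fields::

        preset: mini_scale
        base_seed: 7
        n_realisations: 16
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    preset = raw.pop("preset", "desk_scale")
    cfg = PRESETS[preset](base_seed=int(raw.pop("base_seed", 0)))
    if raw:
        from dataclasses import replace
        cfg = replace(cfg, **raw)
    return cfg
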