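"""Reading and writing pipeline artifacts.

Volumes travel as NIfTI (RAS-aligned, voxel size in the header, masks as
uint8); projection sets as an ``.npz`` container plus a JSON sidecar with
the acquisition geometry; tabular results as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import ActivityMap, AttenuationMap
from .projector import AcquisitionGeometry, ProjectionSet
from .recon import ReconstructedImage


def _affine(voxel_size_cm: float) -> np.ndarray:
    # store in mm, RAS; origin at the volume corner
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_cm * 10.0
    return aff


def save_volume(path, values: np.ndarray, voxel_size_cm: float) -> None:
    data = values.astype(np.uint8) if values.dtype == bool else np.asarray(values, dtype=np.float32)
    img = nib.Nifti1Image(data, _affine(voxel_size_cm))
    nib.save(img, str(path))


def load_volume(path):
    """Returns (values, voxel_size_cm)."""
    img = nib.load(str(path))
    voxel_cm = float(img.header.get_zooms()[0]) / 10.0
    return np.asarray(img.dataobj), voxel_cm


def save_activity(path, activity: ActivityMap) -> None:
    save_volume(path, activity.values, activity.voxel_size_cm)


def load_activity(path) -> ActivityMap:
    values, voxel = load_volume(path)
    return ActivityMap(values=np.asarray(values, dtype=np.float64), voxel_size_cm=voxel)


def load_attenuation(path) -> AttenuationMap:
    values, voxel = load_volume(path)
    return AttenuationMap(values=np.asarray(values, dtype=np.float64), voxel_size_cm=voxel)


def save_image(path, image: ReconstructedImage) -> None:
    save_volume(path, image.values, image.voxel_size_cm)


def save_projections(path, projections: ProjectionSet) -> None:
    """``.npz`` with the count stack + ``.json`` sidecar with the geometry."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), counts=projections.counts)
    g = projections.geometry
    sidecar = {
        "collimator": projections.collimator,
        "n_angles": g.n_angles,
        "arc_degrees": g.arc_degrees,
        "detector_shape": list(g.detector_shape),
        "detector_bin_cm": g.detector_bin_cm,
        "orbit_radii_cm": list(map(float, g.radii())),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_projections(path) -> ProjectionSet:
    path = Path(path)
    counts = np.load(path.with_suffix(".npz"))["counts"]
    meta = json.loads(path.with_suffix(".json").read_text())
    geometry = AcquisitionGeometry(
        n_angles=meta["n_angles"], arc_degrees=meta["arc_degrees"],
        detector_shape=tuple(meta["detector_shape"]),
        detector_bin_cm=meta["detector_bin_cm"],
        orbit_radii_cm=tuple(meta["orbit_radii_cm"]),
    )
    return ProjectionSet(counts=counts, geometry=geometry, collimator=meta["collimator"])
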