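"""Shared fixtures: small phantoms and reconstructions reused across tests.

Everything is generated programmatically; session scope keeps the heavier
artifacts (mini-scale reconstruction) to a single computation.
"""

import numpy as np
import pytest

from cvtspect import (
    LungGeometry,
    PhantomSpec,
    apply_motion_blur,
    build_activity,
    build_lung_mask,
    circular_geometry,
    forward_project,
    place_lesions,
)


@pytest.fixture(scope="session")
def mini_spec():
    """Half-size anatomy on a 64^3 grid at 0.33 cm voxels."""
    return PhantomSpec(grid_shape=(64, 64, 64), voxel_size_cm=0.33,
                       lung_geometry=LungGeometry().scaled(0.5), seed=7)


@pytest.fixture(scope="session")
def mini_mask(mini_spec):
    return build_lung_mask(mini_spec)


@pytest.fixture(scope="session")
def mini_lesions(mini_spec, mini_mask):
    return place_lesions(mini_mask, mini_spec, seed=7)


@pytest.fixture(scope="session")
def tiny_spec():
    """Quarter-size anatomy on a 32^3 grid — fastest end-to-end scale."""
    return PhantomSpec(grid_shape=(32, 32, 32), voxel_size_cm=0.33,
                       lung_geometry=LungGeometry().scaled(0.25), seed=3)


@pytest.fixture(scope="session")
def mini_noiseless_recon(mini_spec, mini_mask):
    """Noiseless healthy mini-scale reconstruction (64 updates, LEHR)."""
    from cvtspect import OsemReconstructor, ReconConfig, build_attenuation

    activity = apply_motion_blur(build_activity(mini_mask, None, mini_spec), mini_spec)
    mu = build_attenuation(mini_spec, mini_mask)
    geom = circular_geometry(64, 64, radius_cm=21.0)
    projs = forward_project(activity, mu, geom, "LEHR")
    recon = OsemReconstructor(mu, geom, "LEHR", ReconConfig(n_subsets=16, n_iterations=4))
    return recon.reconstruct(projs), mini_mask
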