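"""OSEM/MLEM reconstruction properties on small synthetic volumes.

Grids and angle counts are kept deliberately small; angle sets that are
multiples of 90 degrees make the rotation operators exact, so EM theory
(monotone likelihood, fixed points) applies without interpolation slack.
"""

import numpy as np
import pytest

from cvtspect import (
    AttenuationMap,
    OsemReconstructor,
    ProjectionSet,
    ReconConfig,
    SystemModel,
    circular_geometry,
    count_consistency,
    poisson_log_likelihood,
)
from cvtspect.errors import ConfigurationError, ConsistencyError

VOXEL = 0.33


def _sphere_phantom(n, radius_vox, hot=4.0):
    idx = np.arange(n) - (n - 1) / 2
    x, y, z = np.meshgrid(idx, idx, idx, indexing="ij")
    r2 = x**2 + y**2 + z**2
    bkg = (r2 <= (n / 2 - 2) ** 2).astype(float)
    act = bkg.copy()
    act[r2 <= radius_vox**2] = hot
    mu = np.where(bkg > 0, 0.05, 0.0)
    return act, AttenuationMap(mu, VOXEL), r2 <= radius_vox**2, (bkg > 0) & (r2 > (radius_vox + 3) ** 2)


@pytest.fixture(scope="module")
def quad_system():
    """24^3 volume, 4 angles at quarter turns: exact forward/adjoint pair."""
    act, mu, sphere, bkg = _sphere_phantom(24, 4.0)
    geom = circular_geometry(24, 4, VOXEL)
    system = SystemModel(mu, geom, "LEHR")
    return act, mu, geom, system, sphere, bkg


class TestEmCore:
    def test_fixed_point_when_data_match_uniform_start(self, quad_system):
        _, mu, geom, system, _, _ = quad_system
        recon = OsemReconstructor(mu, geom, "LEHR", ReconConfig(n_subsets=1, n_iterations=1),
                                  system=system)
        init = np.where(recon.fov, 1.0, 0.0)
        measured = ProjectionSet(system.forward(init), geom, "LEHR")
        out = recon.reconstruct(measured)
        assert np.allclose(out.values, init, rtol=1e-8, atol=1e-10)

    def test_mlem_likelihood_non_decreasing_on_noiseless_data(self, quad_system):
        act, mu, geom, system, _, _ = quad_system
        measured = ProjectionSet(system.forward(act), geom, "LEHR")
        recon = OsemReconstructor(mu, geom, "LEHR", ReconConfig(n_subsets=1, n_iterations=20),
                                  system=system)
        snaps = recon.reconstruct(measured, snapshots_at=tuple(range(1, 21)))
        lls = [poisson_log_likelihood(snaps[i].values, measured.counts, system)
               for i in range(1, 21)]
        diffs = np.diff(lls)
        assert np.all(diffs >= -1e-6 * np.abs(lls[0]))
        assert lls[-1] > lls[0]

    def test_updates_preserve_non_negativity(self, quad_system):
        act, mu, geom, system, _, _ = quad_system
        rng = np.random.default_rng(0)
        noisy = ProjectionSet(rng.poisson(system.forward(act) * 50).astype(float), geom, "LEHR")
        recon = OsemReconstructor(mu, geom, "LEHR", ReconConfig(n_subsets=2, n_iterations=8),
                                  system=system)
        out = recon.reconstruct(noisy)
        assert np.all(out.values >= 0)
        assert np.all(np.isfinite(out.values))

    def test_provenance_records_updates(self, quad_system):
        act, mu, geom, system, _, _ = quad_system
        measured = ProjectionSet(system.forward(act), geom, "LEHR")
        recon = OsemReconstructor(mu, geom, "LEHR", ReconConfig(n_subsets=4, n_iterations=4),
                                  system=system)
        out = recon.reconstruct(measured)
        assert out.provenance["n_updates"] == 16
        assert out.provenance["n_subsets"] == 4

    def test_subsets_must_divide_angles(self, quad_system):
        _, mu, geom, system, _, _ = quad_system
        with pytest.raises(ConfigurationError):
            OsemReconstructor(mu, geom, "LEHR", ReconConfig(n_subsets=3, n_iterations=1),
                              system=system)


class TestAcceleration:
    def test_osem_one_iteration_matches_mlem_k_iterations_in_contrast(self):
        """k subsets x 1 iteration recovers roughly the contrast of MLEM
        after k iterations (the classic OSEM acceleration property)."""
        act, mu, sphere, bkg = _sphere_phantom(24, 4.0)
        geom = circular_geometry(24, 8, VOXEL)
        system = SystemModel(mu, geom, "LEHR")
        measured = ProjectionSet(system.forward(act), geom, "LEHR")

        def contrast(image):
            return (image[sphere].mean() / image[bkg].mean() - 1.0) / 3.0

        osem = OsemReconstructor(mu, geom, "LEHR", ReconConfig(n_subsets=4, n_iterations=1),
                                 system=system).reconstruct(measured)
        mlem = OsemReconstructor(mu, geom, "LEHR", ReconConfig(n_subsets=1, n_iterations=4),
                                 system=system).reconstruct(measured)
        c_osem, c_mlem = contrast(osem.values), contrast(mlem.values)
        assert c_osem == pytest.approx(c_mlem, rel=0.25)

    def test_contrast_recovery_monotone_in_updates(self):
        """With CDR modelling on noiseless data, hot-sphere contrast
        recovery climbs from 32 to 320 updates to a stable plateau.

        The forward/adjoint pair is matched to interpolation accuracy only,
        so after the plateau the curve may drift by a fraction of a percent
        per iteration; monotonicity is asserted within that drift.
        """
        act, mu, sphere, bkg = _sphere_phantom(32, 5.0)
        geom = circular_geometry(32, 32, VOXEL)
        system = SystemModel(mu, geom, "LEHR")
        measured = ProjectionSet(system.forward(act), geom, "LEHR")
        recon = OsemReconstructor(mu, geom, "LEHR", ReconConfig(n_subsets=16, n_iterations=20),
                                  system=system)
        snaps = recon.reconstruct(measured, snapshots_at=tuple(range(2, 21, 2)))
        curve = np.array([
            (snaps[i].values[sphere].mean() / snaps[i].values[bkg].mean() - 1.0) / 3.0
            for i in range(2, 21, 2)
        ])
        assert np.all(np.diff(curve) >= -0.005)
        assert curve[-1] > curve[0]
        assert curve[-1] >= 0.98 * curve.max()  # stays at the plateau
        assert curve.max() <= 1.1  # recovery approaches but does not overshoot truth


class TestCountConsistency:
    def test_zero_for_perfect_fit(self, quad_system):
        _, mu, geom, system, _, _ = quad_system
        recon = OsemReconstructor(mu, geom, "LEHR", ReconConfig(n_subsets=1, n_iterations=1),
                                  system=system)
        init = np.where(recon.fov, 1.0, 0.0)
        measured = ProjectionSet(system.forward(init), geom, "LEHR")
        out = recon.reconstruct(measured)
        assert count_consistency(out, measured, system) < 1e-8

    def test_small_mismatch_after_64_updates(self, quad_system):
        act, mu, geom, system, _, _ = quad_system
        measured = ProjectionSet(system.forward(act), geom, "LEHR")
        recon = OsemReconstructor(mu, geom, "LEHR", ReconConfig(n_subsets=4, n_iterations=16),
                                  system=system)
        out = recon.reconstruct(measured)
        assert count_consistency(out, measured, system) < 0.05

    def test_empty_measured_data_rejected(self, quad_system):
        _, mu, geom, system, _, _ = quad_system
        empty = ProjectionSet(np.zeros((4, 24, 24)), geom, "LEHR")
        from cvtspect import ReconstructedImage

        img = ReconstructedImage(np.ones((24, 24, 24)), VOXEL)
        with pytest.raises(ConsistencyError):
            count_consistency(img, empty, system)
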