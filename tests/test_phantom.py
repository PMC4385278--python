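"""Phantom geometry, lesion placement, activity/attenuation arithmetic."""

import numpy as np
import pytest
from scipy import signal

from cvtspect import (
    LungGeometry,
    PhantomSpec,
    apply_motion_blur,
    build_activity,
    build_attenuation,
    build_lung_mask,
    build_phantom,
    place_lesions,
)
from cvtspect.errors import ConfigurationError, ConsistencyError, PlacementError
from cvtspect.phantom import body_mask


class TestLungMask:
    def test_volume_hits_target_at_default_scale(self):
        spec = PhantomSpec()  # 128^3, full anatomy, 4.2 l target
        mask = build_lung_mask(spec)
        assert mask.volume_litres == pytest.approx(4.2, rel=0.05)

    def test_half_scale_geometry_scales_volume_with_cube(self, mini_spec, mini_mask):
        # half linear scale -> one eighth of 4.2 l, verified by voxel counting
        assert mini_spec.lung_geometry.target_volume_l == pytest.approx(4.2 / 8)
        counted = mini_mask.values.sum() * mini_spec.voxel_size_cm**3 / 1000.0
        assert counted == pytest.approx(4.2 / 8, rel=0.05)
        assert mini_mask.volume_litres == pytest.approx(counted)

    def test_two_disjoint_lungs_inside_body(self, mini_spec, mini_mask):
        from scipy import ndimage

        assert np.all(body_mask(mini_spec)[mini_mask.values])
        _, n = ndimage.label(mini_mask.values)
        assert n == 2

    def test_degenerate_semi_axes_rejected(self):
        geo = LungGeometry(lung_semi_axes_cm=(0.0, 0.0, 0.0))
        with pytest.raises(ConfigurationError):
            build_lung_mask(PhantomSpec(lung_geometry=geo))

    def test_geometry_exceeding_grid_rejected(self):
        spec = PhantomSpec(grid_shape=(32, 32, 32), voxel_size_cm=0.33)  # full anatomy, tiny grid
        with pytest.raises(ConfigurationError):
            build_lung_mask(spec)


class TestLesions:
    def test_volume_fraction_within_half_point(self, mini_spec, mini_mask, mini_lesions):
        frac = mini_lesions.sum() / mini_mask.values.sum()
        assert 0.095 <= frac <= 0.105

    def test_lesions_contained_in_lung(self, mini_mask, mini_lesions):
        assert not np.any(mini_lesions & ~mini_mask.values)

    def test_zero_fraction_gives_empty_mask(self, mini_spec, mini_mask):
        spec = PhantomSpec(grid_shape=mini_spec.grid_shape, voxel_size_cm=mini_spec.voxel_size_cm,
                           lung_geometry=mini_spec.lung_geometry, lesion_volume_fraction=0.0)
        assert not place_lesions(mini_mask, spec, seed=1).any()

    def test_deterministic_given_seed(self, mini_spec, mini_mask):
        a = place_lesions(mini_mask, mini_spec, seed=42)
        b = place_lesions(mini_mask, mini_spec, seed=42)
        assert np.array_equal(a, b)
        c = place_lesions(mini_mask, mini_spec, seed=43)
        assert not np.array_equal(a, c)

    def test_unreachable_fraction_reports_achieved(self, tiny_spec):
        mask = build_lung_mask(tiny_spec)
        spec = PhantomSpec(grid_shape=tiny_spec.grid_shape, voxel_size_cm=tiny_spec.voxel_size_cm,
                           lung_geometry=tiny_spec.lung_geometry, lesion_volume_fraction=0.6)
        with pytest.raises(PlacementError) as exc:
            place_lesions(mask, spec, seed=1)
        assert 0.0 <= exc.value.achieved_fraction < 0.6


class TestActivity:
    def test_healthy_distribution_is_homogeneous(self, mini_spec, mini_mask):
        act = build_activity(mini_mask, None, mini_spec)
        assert np.all(act.values[mini_mask.values] == 1.0)
        assert np.all(act.values[~mini_mask.values] == 0.0)

    def test_copd_total_is_five_percent_below_healthy(self, mini_spec, mini_mask, mini_lesions):
        healthy = build_activity(mini_mask, None, mini_spec)
        copd = build_activity(mini_mask, mini_lesions, mini_spec)
        reduction = 1.0 - copd.total() / healthy.total()
        frac = mini_lesions.sum() / mini_mask.values.sum()
        # reduction = volume fraction x (1 - concentration fraction)
        assert reduction == pytest.approx(frac * 0.5, abs=1e-12)
        assert reduction == pytest.approx(0.05, abs=0.005)

    def test_unit_concentration_fraction_equals_healthy(self, mini_spec, mini_mask, mini_lesions):
        spec = PhantomSpec(grid_shape=mini_spec.grid_shape, voxel_size_cm=mini_spec.voxel_size_cm,
                           lung_geometry=mini_spec.lung_geometry, lesion_concentration_fraction=1.0)
        healthy = build_activity(mini_mask, None, spec)
        full = build_activity(mini_mask, mini_lesions, spec)
        assert np.array_equal(healthy.values, full.values)

    def test_lesion_outside_lung_rejected(self, mini_spec, mini_mask):
        bad = np.zeros_like(mini_mask.values)
        bad[0, 0, 0] = True
        with pytest.raises(ConsistencyError):
            build_activity(mini_mask, bad, mini_spec)


class TestAttenuation:
    def test_tissue_values(self, mini_spec, mini_mask, mini_lesions):
        mu = build_attenuation(mini_spec, mini_mask)
        assert np.all(mu.values[mini_mask.values] == 0.04)
        assert np.all(mu.values[mini_lesions] == 0.04)  # lesions keep lung density
        body = body_mask(mini_spec)
        assert np.all(mu.values[body & ~mini_mask.values] == 0.15)
        assert np.all(mu.values[~body] == 0.0)

    def test_missing_tissue_label_rejected(self, mini_spec, mini_mask):
        spec = PhantomSpec(grid_shape=mini_spec.grid_shape, voxel_size_cm=mini_spec.voxel_size_cm,
                           lung_geometry=mini_spec.lung_geometry, tissue_mu={"air": 0.0})
        with pytest.raises(ConfigurationError):
            build_attenuation(spec, mini_mask)


class TestMotionBlur:
    def test_zero_fwhm_is_identity(self, mini_spec, mini_mask):
        spec = PhantomSpec(grid_shape=mini_spec.grid_shape, voxel_size_cm=mini_spec.voxel_size_cm,
                           lung_geometry=mini_spec.lung_geometry, motion_blur_fwhm_cm=(0, 0, 0))
        act = build_activity(mini_mask, None, spec)
        assert np.array_equal(apply_motion_blur(act, spec).values, act.values)

    def test_total_activity_conserved(self, mini_spec, mini_mask):
        act = build_activity(mini_mask, None, mini_spec)
        blurred = apply_motion_blur(act, mini_spec)
        assert blurred.total() == pytest.approx(act.total(), rel=1e-3)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ConfigurationError):
            PhantomSpec(motion_blur_fwhm_cm=(-1.0, 0.3, 0.3))

    def test_blurred_lesion_contrast_matches_direct_convolution(self):
        """A 1-cm lesion blurred with 1-cm FWHM loses most of its 50% depth;
        oracle: direct FFT convolution with an explicitly built Gaussian."""
        voxel, fwhm = 0.165, 1.0
        n = 61
        c = (n - 1) / 2
        idx = np.arange(n) - c
        x, y, z = np.meshgrid(idx, idx, idx, indexing="ij")
        r = np.sqrt(x**2 + y**2 + z**2) * voxel
        vol = np.where(r <= 0.5, 0.5, 1.0)  # lesion at 50% in unit background
        sigma = fwhm / 2.354820045 / voxel
        k = np.arange(-15, 16)
        g1 = np.exp(-0.5 * (k / sigma) ** 2)
        g1 /= g1.sum()
        kernel = g1[:, None, None] * g1[None, :, None] * g1[None, None, :]
        oracle = signal.fftconvolve(vol, kernel, mode="same")

        spec = PhantomSpec(grid_shape=(n, n, n), voxel_size_cm=voxel,
                           motion_blur_fwhm_cm=(fwhm, fwhm, fwhm))
        from cvtspect import ActivityMap

        blurred = apply_motion_blur(ActivityMap(vol.copy(), voxel), spec)
        centre = blurred.values[int(c), int(c), int(c)]
        assert centre == pytest.approx(oracle[int(c), int(c), int(c)], rel=1e-3)
        assert centre > 0.5  # contrast is shallower than the unblurred 50%


def test_phantom_build_is_bit_reproducible(tiny_spec):
    m1, l1, a1, mu1 = build_phantom(tiny_spec, diseased=True, seed=5)
    m2, l2, a2, mu2 = build_phantom(tiny_spec, diseased=True, seed=5)
    assert np.array_equal(m1.values, m2.values)
    assert np.array_equal(l1, l2)
    assert np.array_equal(a1.values, a2.values)
    assert np.array_equal(mu1.values, mu2.values)
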