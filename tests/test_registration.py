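"""Registration: brightness correction, XY/Z shifts, closed loop, warping."""

import numpy as np
import pytest

from catrack import registration as reg
from catrack import synthetic as syn
from catrack.masks import CellMask


def checker_image(seed=0, shape=(64, 64)):
    rng = np.random.default_rng(seed)
    from scipy.ndimage import gaussian_filter
    return gaussian_filter(rng.standard_normal(shape), 2.0)


class TestBrightnessCorrect:
    def test_constant_image_maps_to_ones(self):
        img = np.full((40, 40), 7.0)
        assert np.allclose(reg.brightness_correct(img), 1.0)

    def test_smooth_gradient_flattened(self):
        ramp = np.linspace(10, 20, 64)[None, :] * np.ones((64, 1))
        out = reg.brightness_correct(ramp)
        interior = out[:, 15:-15]
        assert np.allclose(interior, 1.0, atol=0.05)

    def test_impulse_preserved_on_flat_background(self):
        img = np.full((64, 64), 2.0)
        img[32, 32] = 50.0
        out = reg.brightness_correct(img)
        # the 25x25 median at the impulse is the background level
        assert out[32, 32] == pytest.approx(25.0)
        assert np.allclose(np.delete(out.ravel(), 32 * 64 + 32), 1.0)

    def test_kernel_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            reg.brightness_correct(np.ones((10, 10)), kernel_px=25)


class TestRigidShiftXY:
    def test_identity(self):
        img = checker_image(1)
        s = reg.rigid_shift_xy(img, img)
        assert (s.dx_px, s.dy_px) == (0.0, 0.0)
        assert s.peak_corr == pytest.approx(1.0)

    @pytest.mark.parametrize("t", [(3, -2), (-5, 0), (7, 7), (0, -9)])
    def test_equivariance_integer_roll(self, t):
        """Shifting the image by t must be undone by a −t correction."""
        img = checker_image(2)
        moved = np.roll(img, t, axis=(0, 1))
        s = reg.rigid_shift_xy(moved, img, subpixel=False)
        assert (s.dy_px, s.dx_px) == (-t[0], -t[1])
        assert s.peak_corr == pytest.approx(1.0)

    def test_shift_reported_in_um(self):
        img = checker_image(3)
        moved = np.roll(img, (2, 4), axis=(0, 1))
        s = reg.rigid_shift_xy(moved, img, subpixel=False,
                               pixel_size_um=(1.1, 0.9))
        assert s.dx_um == pytest.approx(-4 * 1.1)
        assert s.dy_um == pytest.approx(-2 * 0.9)

    def test_uncorrelated_noise_flagged(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal((64, 64))
        b = rng.standard_normal((64, 64))
        s = reg.rigid_shift_xy(a, b)
        assert s.peak_corr < 0.5
        assert "low_correlation" in s.flags

    def test_flat_input_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            reg.rigid_shift_xy(np.ones((64, 64)), checker_image())


class TestBestXYOverStack:
    def _stack(self, images):
        arr = np.stack(images)[:, None]
        return syn.StructuralStack(images=arr,
                                   z_offsets_um=np.arange(len(images), dtype=float),
                                   pixel_size_um=(1.0, 1.0),
                                   plane_spacing_um=30.0)

    def test_all_planes_identical_zero_shift(self):
        img = checker_image(5)
        stack = self._stack([img] * 4)
        s = reg.best_xy_over_stack(stack, img)
        assert (s.dx_px, s.dy_px) == (0.0, 0.0)

    def test_in_focus_plane_wins(self):
        from scipy.ndimage import gaussian_filter
        img = checker_image(6)
        moved = np.roll(img, (4, -3), axis=(0, 1))
        blurred = gaussian_filter(moved, 4.0)
        stack = self._stack([blurred, moved, blurred])
        s = reg.best_xy_over_stack(stack, img, subpixel=False)
        assert s.source_plane == 1
        assert (s.dy_px, s.dx_px) == (-4, 3)

    def test_empty_stack_rejected(self):
        stack = syn.StructuralStack(images=np.zeros((0, 1, 8, 8)),
                                    z_offsets_um=np.zeros(0),
                                    pixel_size_um=(1, 1),
                                    plane_spacing_um=30.0)
        with pytest.raises(ValueError):
            reg.best_xy_over_stack(stack, np.zeros((8, 8)))


class TestGaussianZFit:
    GRID = np.arange(30.0, -35.0, -5.0)[::-1]  # monotone increasing

    def gauss(self, z, a, b, mu, sigma):
        return a * np.exp(-((z - mu) ** 2) / (2 * sigma ** 2)) + b

    def test_noiseless_recovery(self):
        c = self.gauss(self.GRID, 0.5, 0.2, 7.5, 10.0)
        fit = reg.fit_linear_offset_gaussian(self.GRID, c)
        assert fit.amplitude == pytest.approx(0.5, abs=1e-6)
        assert fit.offset == pytest.approx(0.2, abs=1e-6)
        assert fit.center_um == pytest.approx(7.5, abs=1e-6)
        assert fit.width_um == pytest.approx(10.0, abs=1e-6)

    def test_symmetric_profile_centered_at_zero(self):
        c = self.gauss(self.GRID, 0.8, 0.1, 0.0, 12.0)
        fit = reg.fit_linear_offset_gaussian(self.GRID, c)
        assert fit.center_um == pytest.approx(0.0, abs=1e-8)

    def test_flat_profile_no_axial_peak(self):
        with pytest.raises(ValueError, match="no axial peak"):
            reg.fit_linear_offset_gaussian(self.GRID,
                                           np.full(self.GRID.size, 0.3))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            reg.fit_linear_offset_gaussian([0, 5, 10], [0.1, 0.5, 0.1])

    def test_noisy_center_recovery_rate(self):
        """With corr noise σ=0.02 the center lands within 2.5 μm in
        at least 95% of 200 seeded fits."""
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            mu = rng.uniform(-15, 15)
            c = self.gauss(self.GRID, 0.5, 0.2, mu, 10.0)
            c = c + 0.02 * rng.standard_normal(c.size)
            try:
                fit = reg.fit_linear_offset_gaussian(self.GRID, c)
                if abs(fit.center_um - mu) <= 2.5:
                    hits += 1
            except ValueError:
                pass
        assert hits >= 190


class TestEstimateZShift:
    @pytest.mark.parametrize("true_dz", [0.0, 10.0])
    def test_recovers_axial_drift(self, small_field, true_dz):
        ref = syn.render_structural_stack(small_field, seed=1, frames_per_z=1,
                                          noise_sd=0.0)
        stack = syn.render_structural_stack(small_field, seed=1,
                                            frames_per_z=1, noise_sd=0.0,
                                            drift_um=(0, 0, true_dz))
        ref_img = ref.images[np.argmin(np.abs(ref.z_offsets_um)), 0]
        dz, fit = reg.estimate_z_shift(stack, ref_img)
        tol = 1.0 if true_dz == 0 else 2.5
        assert abs(dz - true_dz) <= tol
        assert fit.width_um > 0

    def test_out_of_capture_range(self, small_field):
        ref = syn.render_structural_stack(small_field, seed=1, frames_per_z=1,
                                          noise_sd=0.0)
        stack = syn.render_structural_stack(small_field, seed=1,
                                            frames_per_z=1, noise_sd=0.0,
                                            drift_um=(0, 0, 50.0))
        ref_img = ref.images[np.argmin(np.abs(ref.z_offsets_um)), 0]
        with pytest.raises(ValueError, match="no axial peak"):
            reg.estimate_z_shift(stack, ref_img)


class TestAlignIterative:
    def _setup(self, drift, seed=21):
        field = syn.generate_field(25, seed=seed, fov_um=(128, 128),
                                   pixel_size_um=(1.0, 1.0), n_planes=1,
                                   structural_fraction=0.7)
        ref = syn.render_structural_stack(field, seed=seed + 1,
                                          frames_per_z=2)
        acquire = syn.make_acquire(field, drift, seed=seed + 1,
                                   frames_per_z=2)
        return ref, acquire

    def test_zero_drift_converges_immediately(self):
        ref, acquire = self._setup((0.0, 0.0, 0.0))
        res = reg.align_iterative(acquire, ref)
        assert res.converged and res.n_iter == 1
        assert np.allclose(res.final_position_um, 0.0, atol=2.0)

    def test_known_drift_recovered_within_three_iterations(self):
        drift = (12.0, -8.0, 10.0)
        ref, acquire = self._setup(drift)
        res = reg.align_iterative(acquire, ref)
        assert res.converged and res.n_iter <= 3
        final = res.iterations[-1]
        assert all(abs(final[k]) < 5.0 for k in ("dx_um", "dy_um", "dz_um"))
        assert np.allclose(res.final_position_um[:2], drift[:2], atol=1.0)
        assert abs(res.final_position_um[2] - drift[2]) <= 2.5

    def test_residuals_non_increasing(self):
        ref, acquire = self._setup((14.0, 9.0, -12.0))
        res = reg.align_iterative(acquire, ref)
        mags = [np.hypot(it["dx_um"], it["dy_um"]) for it in res.iterations]
        assert all(b <= a + 1e-6 for a, b in zip(mags, mags[1:]))

    def test_unreachable_drift_does_not_converge(self):
        ref, acquire = self._setup((60.0, 0.0, 0.0))
        res = reg.align_iterative(acquire, ref, max_iter=3, max_shift_px=15)
        assert not res.converged
        assert res.n_iter == 3


class TestPiecewiseRigid:
    def test_identical_images_zero_field(self):
        img = checker_image(7, (96, 96))
        field = reg.piecewise_rigid_map(img, img, patch_grid=(3, 3))
        assert np.allclose(field.shifts_px, 0.0)

    def test_global_translation_uniform_field(self):
        img = checker_image(8, (96, 96))
        moved = np.roll(img, (4, -6), axis=(0, 1))
        field = reg.piecewise_rigid_map(moved, img, patch_grid=(2, 2),
                                        max_shift_px=10, subpixel=False)
        assert np.allclose(field.shifts_px[..., 0], -4)
        assert np.allclose(field.shifts_px[..., 1], 6)

    def test_1x1_grid_equals_rigid(self):
        img = checker_image(9, (64, 64))
        moved = np.roll(img, (3, 5), axis=(0, 1))
        field = reg.piecewise_rigid_map(moved, img, patch_grid=(1, 1))
        rigid = reg.rigid_shift_xy(moved, img)
        assert field.shifts_px[0, 0, 0] == pytest.approx(rigid.dy_px)
        assert field.shifts_px[0, 0, 1] == pytest.approx(rigid.dx_px)

    def test_small_patches_rejected(self):
        with pytest.raises(ValueError, match="patch"):
            reg.piecewise_rigid_map(np.zeros((32, 32)), np.zeros((32, 32)),
                                    patch_grid=(8, 8))

    def test_init_shift_included_in_field(self):
        img = checker_image(10, (96, 96))
        moved = np.roll(img, (12, 0), axis=(0, 1))
        field = reg.piecewise_rigid_map(moved, img, patch_grid=(2, 2),
                                        init_shift_px=(-12, 0),
                                        max_shift_px=4)
        assert np.allclose(field.shifts_px[..., 0], -12)


class TestApplyShiftField:
    def _const_field(self, dy, dx, shape=(64, 64)):
        return reg.ShiftField(shifts_px=np.array([[[dy, dx]]], dtype=float),
                              row_centers=np.array([shape[0] / 2]),
                              col_centers=np.array([shape[1] / 2]),
                              shape=shape)

    def test_zero_field_is_identity_on_masks(self):
        m = CellMask(pixels=[(5, 5), (5, 6), (6, 5)])
        out = reg.apply_shift_field(m, self._const_field(0, 0))
        assert set(map(tuple, out.pixels)) == set(map(tuple, m.pixels))

    def test_integer_translation_exact(self):
        m = CellMask(pixels=[(10, 10), (10, 11), (11, 10), (11, 11)])
        out = reg.apply_shift_field(m, self._const_field(3, -2))
        assert set(map(tuple, out.pixels)) == {(13, 8), (13, 9), (14, 8),
                                               (14, 9)}

    def test_border_mask_clipped_and_flagged(self):
        m = CellMask(pixels=[(62, 62), (62, 63), (63, 62), (63, 63)])
        out = reg.apply_shift_field(m, self._const_field(3, 3))
        assert out.area_px2 < m.area_px2
        assert "clipped" in out.flags or "out_of_frame" in out.flags

    def test_fully_out_of_frame_flagged_empty(self):
        m = CellMask(pixels=[(62, 62), (63, 63)])
        out = reg.apply_shift_field(m, self._const_field(10, 10))
        assert out.area_px2 == 0
        assert "out_of_frame" in out.flags

    def test_image_warp_matches_roll_in_interior(self):
        img = checker_image(11)
        out = reg.apply_shift_field(img, self._const_field(2, -3))
        rolled = np.roll(img, (2, -3), axis=(0, 1))
        assert np.allclose(out[10:-10, 10:-10], rolled[10:-10, 10:-10],
                           atol=1e-8)
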