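import numpy as np
import pytest
from scipy import ndimage

from mechprop import synth, tfm
from mechprop.fields import VectorField2D


class TestDriftCorrection:
    def test_known_translation_removed(self):
        rng = np.random.default_rng(0)
        base = ndimage.gaussian_filter(rng.normal(size=(128, 128)), 2)
        # exact (periodic) subpixel translation
        shifted = np.fft.ifftn(ndimage.fourier_shift(np.fft.fftn(base),
                                                     (2.3, -1.7))).real
        corrected, shifts = tfm.correct_drift(np.stack([base, shifted]))
        np.testing.assert_allclose(shifts[1], [-2.3, 1.7], atol=0.05)
        resid = np.abs(corrected[1][10:-10, 10:-10] -
                       base[10:-10, 10:-10]).max()
        assert resid < 0.05 * np.abs(base).max()

    def test_aligned_stack_is_identity(self):
        rng = np.random.default_rng(1)
        base = ndimage.gaussian_filter(rng.normal(size=(64, 64)), 2)
        corrected, shifts = tfm.correct_drift(np.stack([base, base]))
        np.testing.assert_allclose(shifts, 0.0, atol=1e-3)


class TestRecoverDisplacement:
    def test_uniform_shift_recovered_everywhere(self, piv_config):
        rng = np.random.default_rng(2)
        disp = VectorField2D(np.full((80, 80), 1.0), np.zeros((80, 80)), 0.5,
                             kind="displacement")
        pair = synth.render_bead_images(disp, 0.3, noise_sigma=0.0, seed=5,
                                        pixel_size_um=0.5)
        sc = tfm.recover_displacement(pair.reference, pair.deformed[0],
                                      piv_config, 0.5)
        err = np.hypot(sc.u_um - 1.0, sc.v_um)
        assert np.quantile(err, 0.95) < 0.05

    def test_synthetic_field_round_trip_rms(self, corner_displacement,
                                            true_displacement_interp,
                                            piv_config):
        """Generator round trip: noise-free rendering recovered with
        RMS error < 0.1 µm."""
        pair = synth.render_bead_images(corner_displacement, 0.4,
                                        psf_sigma_um=0.45, noise_sigma=0.0,
                                        seed=1, pixel_size_um=0.3)
        sc = tfm.recover_displacement(pair.reference, pair.deformed[0],
                                      piv_config, 0.3,
                                      origin_um=corner_displacement.origin_um)
        truth = true_displacement_interp(sc.x_um, sc.y_um)
        err = np.hypot(sc.u_um - truth[:, 0], sc.v_um - truth[:, 1])
        assert np.sqrt(np.mean(err**2)) < 0.1

    def test_shape_mismatch_rejected(self, piv_config):
        with pytest.raises(ValueError):
            tfm.recover_displacement(np.zeros((32, 32)), np.zeros((40, 32)),
                                     piv_config, 0.3)


class TestFilterOutliers:
    def _uniform_scatter(self, value=(0.5, 0.0), n=7):
        x, y = np.meshgrid(np.arange(n, dtype=float),
                           np.arange(n, dtype=float))
        u = np.full(n * n, value[0])
        v = np.full(n * n, value[1])
        return tfm.ScatteredField(x.ravel(), y.ravel(), u, v)

    def test_magnitude_outlier_replaced_by_neighbor_mean(self):
        sc = self._uniform_scatter()
        sc.u_um[24] = 3.0  # exceeds the 2.5 µm discard threshold
        out = tfm.filter_outliers(sc)
        assert np.isclose(out.u_um[24], 0.5)

    def test_neighbor_difference_outlier_replaced(self):
        sc = self._uniform_scatter()
        sc.u_um[24] = 0.5 + 1.5  # differs from neighbours by 1.5 µm > 1 µm
        out = tfm.filter_outliers(sc)
        assert np.isclose(out.u_um[24], 0.5)

    def test_uniform_field_unchanged(self):
        sc = self._uniform_scatter()
        out = tfm.filter_outliers(sc)
        np.testing.assert_array_equal(out.u_um, sc.u_um)

    def test_never_increases_max_magnitude(self):
        rng = np.random.default_rng(3)
        sc = tfm.ScatteredField(rng.uniform(0, 20, 60), rng.uniform(0, 20, 60),
                                rng.normal(0, 1.2, 60), rng.normal(0, 1.2, 60))
        before = np.hypot(sc.u_um, sc.v_um).max()
        out = tfm.filter_outliers(sc)
        assert np.hypot(out.u_um, out.v_um).max() <= before + 1e-12

    def test_idempotent_on_own_output(self):
        sc = self._uniform_scatter()
        sc.u_um[24] = 3.0
        once = tfm.filter_outliers(sc)
        twice = tfm.filter_outliers(once)
        np.testing.assert_allclose(twice.u_um, once.u_um)

    def test_grid_field_supported(self):
        f = VectorField2D(np.full((6, 6), 0.5), np.zeros((6, 6)), 1.0)
        f.vx[3, 3] = 5.0
        out = tfm.filter_outliers(f)
        assert np.isclose(out.vx[3, 3], 0.5)


class TestInterpolateToGrid:
    def test_affine_field_reproduced_exactly(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 20, 200)
        y = rng.uniform(0, 20, 200)
        u = 0.1 * x - 0.05 * y + 0.3
        v = 0.02 * x + 0.07 * y - 0.1
        grid = tfm.interpolate_to_grid(tfm.ScatteredField(x, y, u, v), 1.3,
                                       extent=(2, 18, 2, 18))
        X, Y = grid.coords()
        np.testing.assert_allclose(grid.vx, 0.1 * X - 0.05 * Y + 0.3,
                                   atol=1e-12)

    def test_constant_field(self):
        rng = np.random.default_rng(5)
        x, y = rng.uniform(0, 10, 50), rng.uniform(0, 10, 50)
        grid = tfm.interpolate_to_grid(
            tfm.ScatteredField(x, y, np.full(50, 2.0), np.zeros(50)), 1.0,
            extent=(2, 8, 2, 8))
        np.testing.assert_allclose(grid.vx, 2.0, atol=1e-12)

    def test_outside_hull_zero_filled(self):
        sc = tfm.ScatteredField(np.array([5., 6., 5.5]),
                                np.array([5., 5., 6.]),
                                np.ones(3), np.ones(3))
        grid = tfm.interpolate_to_grid(sc, 1.0, extent=(0, 10, 0, 10))
        assert grid.vx[0, 0] == 0.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            tfm.interpolate_to_grid(
                tfm.ScatteredField(np.array([1.0]), np.array([1.0]),
                                   np.array([0.0]), np.array([0.0])), 1.0)

    def test_smooth_field_rms_under_2pct(self):
        rng = np.random.default_rng(6)
        x, y = rng.uniform(0, 40, 1500), rng.uniform(0, 40, 1500)
        u = np.sin(x / 6) * np.cos(y / 7)
        grid = tfm.interpolate_to_grid(
            tfm.ScatteredField(x, y, u, 0 * u), 1.3, extent=(3, 37, 3, 37))
        X, Y = grid.coords()
        truth = np.sin(X / 6) * np.cos(Y / 7)
        rms = np.sqrt(np.mean((grid.vx - truth) ** 2))
        assert rms < 0.02 * np.sqrt(np.mean(truth**2))


class TestFTTC:
    def test_zero_displacement_zero_traction(self, substrate):
        u = VectorField2D(np.zeros((32, 32)), np.zeros((32, 32)), 1.3)
        t = tfm.fttc(u, substrate)
        assert np.all(t.vx == 0)

    def test_forward_inverse_round_trip(self, corner_traction,
                                        corner_displacement, substrate):
        rec = tfm.fttc(corner_displacement, substrate, reg_lambda=0.0)
        num = np.sqrt(np.mean((rec.vx - corner_traction.vx) ** 2 +
                              (rec.vy - corner_traction.vy) ** 2))
        den = np.sqrt(np.mean(corner_traction.vx**2 + corner_traction.vy**2))
        assert num / den < 0.10

    def test_recovered_net_force_balances(self, corner_displacement,
                                          substrate):
        rec = tfm.fttc(corner_displacement, substrate)
        total_abs = np.abs(rec.net_force_N()).sum()
        scale = (rec.magnitude().sum() * rec.dA_um2) * 1e-12
        assert total_abs < 0.01 * scale

    def test_negative_regularization_rejected(self, substrate):
        u = VectorField2D(np.zeros((16, 16)), np.zeros((16, 16)), 1.3)
        with pytest.raises(ValueError):
            tfm.fttc(u, substrate, reg_lambda=-1.0)


class TestStrainEnergy:
    def test_zero_displacement_zero_energy(self):
        t = VectorField2D(np.ones((10, 10)), np.zeros((10, 10)), 1.0,
                          kind="traction")
        u = VectorField2D(np.zeros((10, 10)), np.zeros((10, 10)), 1.0)
        assert tfm.strain_energy(t, u).strain_energy_J == 0.0

    def test_uniform_parallel_fields_closed_form(self):
        # ½|T||u|A: 100 Pa × 0.5 µm × 100 µm² → ½·5000 Pa·µm³ = 2.5e-15 J
        t = VectorField2D(np.full((10, 10), 100.0), np.zeros((10, 10)), 1.0,
                          kind="traction")
        u = VectorField2D(np.full((10, 10), 0.5), np.zeros((10, 10)), 1.0)
        rec = tfm.strain_energy(t, u)
        assert np.isclose(rec.strain_energy_J, 2.5e-15)
        assert np.isclose(rec.left_energy_J + rec.right_energy_J,
                          rec.strain_energy_J)

    def test_random_fields_against_direct_sum(self):
        rng = np.random.default_rng(7)
        tv = rng.normal(size=(12, 14))
        uv = rng.normal(size=(12, 14))
        t = VectorField2D(tv, 0 * tv, 2.0, kind="traction")
        u = VectorField2D(uv, 0 * uv, 2.0)
        expected = 0.5 * np.sum(tv * uv) * 4.0 * 1e-18
        assert np.isclose(tfm.strain_energy(t, u).strain_energy_J, expected,
                          rtol=1e-12)

    def test_quadratic_amplitude_scaling(self):
        rng = np.random.default_rng(8)
        tv = rng.normal(size=(8, 8))
        t1 = VectorField2D(tv, 0 * tv, 1.0, kind="traction")
        u1 = VectorField2D(0.1 * tv, 0 * tv, 1.0)
        t2 = VectorField2D(2 * tv, 0 * tv, 1.0, kind="traction")
        u2 = VectorField2D(0.2 * tv, 0 * tv, 1.0)
        e1 = tfm.strain_energy(t1, u1).strain_energy_J
        e2 = tfm.strain_energy(t2, u2).strain_energy_J
        assert np.isclose(e2, 4 * e1)

    def test_mismatched_grids_rejected(self):
        t = VectorField2D(np.ones((8, 8)), np.zeros((8, 8)), 1.0,
                          kind="traction")
        u = VectorField2D(np.ones((9, 8)), np.zeros((9, 8)), 1.0)
        with pytest.raises(ValueError):
            tfm.strain_energy(t, u)


class TestRelativeStrainEnergy:
    def test_step_plateau(self):
        series = np.concatenate([np.full(20, 2.0), np.full(10, 3.0)])
        rel = tfm.relative_strain_energy(series, baseline_frames=20)
        np.testing.assert_allclose(rel[:20], 0.0)
        np.testing.assert_allclose(rel[20:], 0.5)

    def test_constant_series_is_zero(self):
        rel = tfm.relative_strain_energy(np.full(30, 5.0), 20)
        np.testing.assert_allclose(rel, 0.0)

    def test_cohort_baseline_divisor(self):
        # two cells with baselines E0 and 3E0 → both divided by 2E0
        series = np.concatenate([np.full(20, 1.0), np.full(5, 2.0)])
        rel = tfm.relative_strain_energy(series, 20,
                                         cohort_baselines=[1.0, 3.0])
        np.testing.assert_allclose(rel[20:], 0.5)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            tfm.relative_strain_energy(np.ones(10), 20)
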