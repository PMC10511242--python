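import numpy as np
import pytest

from mechprop import activesim as asim
from mechprop import msm
from mechprop import pipeline as pl


def energy_series(out, params):
    return np.array([0.5 * params.substrate_stiffness *
                     np.sum(d.vx**2 + d.vy**2) * d.grid_spacing_um**2
                     for d in out["displacement"]])


@pytest.fixture(scope="module")
def short_params():
    return asim.FemParams(n_frames=12, activation_window=(6, 12),
                          mesh_resolution_um=3.0)


class TestFemParams:
    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            asim.FemParams(n_frames=10, activation_window=(8, 12))

    def test_invalid_rheology_rejected(self):
        with pytest.raises(ValueError):
            asim.FemParams(body_rheology="plastic")

    def test_nonpositive_modulus_rejected(self):
        with pytest.raises(ValueError):
            asim.FemParams(sheet_modulus=-1.0)


class TestSimulateFem:
    def test_no_activation_is_stationary(self, short_params):
        p = short_params.replace(activation_increment=0.0)
        out = asim.simulate_fem(p, epsilon=0.0, width_um=45, height_um=45)
        m0 = out["traction"][0].magnitude()
        m1 = out["traction"][-1].magnitude()
        assert np.abs(m1 - m0).max() < 1e-10 * m0.max()

    def test_full_coupling_left_right_symmetric(self, short_params):
        out = asim.simulate_fem(short_params, epsilon=1.0, width_um=45,
                                height_um=45)
        sm = out["stress"][-1]
        np.testing.assert_allclose(sm.sxx, sm.sxx[:, ::-1], atol=1e-8)
        np.testing.assert_allclose(sm.syy, sm.syy[:, ::-1], atol=1e-8)

    def test_1d_strip_matches_sinh_solution(self):
        """Steady state of a uniformly active narrow strip on a spring
        foundation: u(x) = −(σa/Es)·ℓ·sinh(x/ℓ)/cosh(L/2ℓ), ℓ² = Es/Y."""
        p = asim.FemParams(sheet_poisson=0.0, n_frames=1,
                           activation_window=(0, 1),
                           activation_increment=0.0,
                           mesh_resolution_um=0.6)
        out = asim.simulate_fem(p, epsilon=0.0, width_um=60, height_um=4.8)
        u = out["displacement"][0]
        ell = np.sqrt(p.sheet_modulus / p.substrate_stiffness)
        X, _ = u.coords()
        x = X[0]
        row = u.vx[u.shape[0] // 2]
        pred = -(p.baseline_active_stress / p.sheet_modulus) * ell * \
            np.sinh(x / ell) / np.cosh(30.0 / ell)
        err = np.sqrt(np.mean((row - pred) ** 2) / np.mean(pred**2))
        assert err < 0.02

    def test_invalid_epsilon_rejected(self, short_params):
        with pytest.raises(ValueError):
            asim.simulate_fem(short_params, epsilon=2.0, width_um=45,
                              height_um=45)


class TestRheologyDichotomy:
    def test_kelvin_voigt_returns_to_baseline(self):
        p = asim.FemParams(n_frames=60, activation_window=(20, 30),
                           mesh_resolution_um=2.5)
        e = energy_series(asim.simulate_fem(p, epsilon=1.0, width_um=45,
                                            height_um=45), p)
        base = e[:20].mean()
        assert e[29] / base - 1 > 0.05          # clear rise under activation
        assert abs(e[-1] / base - 1) < 0.05     # homeostatic return

    def test_maxwell_keeps_decaying(self):
        p = asim.FemParams(n_frames=60, activation_window=(20, 30),
                           mesh_resolution_um=2.5,
                           body_rheology="maxwell_after_activation")
        e = energy_series(asim.simulate_fem(p, epsilon=1.0, width_um=45,
                                            height_um=45), p)
        base = e[:20].mean()
        assert abs(e[-1] / base - 1) > 0.20     # stays displaced
        # the decay continues even after the activation is stopped
        assert np.all(np.diff(e[31:]) < 0)


class TestSimulateContour:
    def test_no_activation_keeps_circular_arc(self):
        out = asim.simulate_contour(epsilon=0.0, n_frames=2,
                                    activation_window=(1, 2), delta_rel=0.0)
        sh = out["shapes"][-1]
        yc = 22.5 + np.sqrt(30.0**2 - 22.5**2)
        r = np.hypot(sh[:, 0], sh[:, 1] - yc)
        np.testing.assert_allclose(r, 30.0, atol=1e-6)

    def test_symmetric_activation_symmetric_distance(self):
        out = asim.simulate_contour(epsilon=1.0, n_frames=4,
                                    activation_window=(2, 4))
        d = out["distance"][-1]
        np.testing.assert_allclose(d, d[::-1], atol=1e-4)

    def test_activation_pulls_contour_inward(self):
        out = asim.simulate_contour(epsilon=1.0, n_frames=4,
                                    activation_window=(2, 4))
        assert out["distance"][-1].min() < out["distance"][0].min()


@pytest.fixture(scope="module")
def curves():
    p = asim.FemParams(n_frames=24, activation_window=(12, 22),
                       mesh_resolution_um=2.5)
    grid = np.linspace(-1, 1, 9)
    return {src: {ch: asim.coupling_curve(ch, grid, params=p,
                                          response_source=src)
                  for ch in ("sigma_xx", "sigma_yy")}
            for src in ("model_stress", "msm")}


@pytest.fixture(scope="module")
def yy_curve(curves):
    return curves["msm"]["sigma_yy"]


class TestCouplingCurve:

    def test_symmetry_anchor_at_full_coupling(self, curves):
        for ch in ("sigma_xx", "sigma_yy"):
            c = curves["model_stress"][ch]
            assert np.isclose(c.normalized_right_response[-1], 0.5,
                              atol=1e-9)

    def test_monotone_over_grid(self, curves):
        for src in curves:
            for c in curves[src].values():
                assert c.is_monotone()

    def test_xx_curve_dominates_yy_at_low_coupling(self, curves):
        """x-forces balance across the junction (tug of war), so the
        passive σxx response spreads further into the receiver half than
        the locally balanced σyy response."""
        cxx = curves["msm"]["sigma_xx"]
        cyy = curves["msm"]["sigma_yy"]
        common = np.intersect1d(cxx.epsilon_grid, cyy.epsilon_grid)
        common = common[common <= 0.5]
        rxx = np.interp(common, cxx.epsilon_grid,
                        cxx.normalized_right_response)
        ryy = np.interp(common, cyy.epsilon_grid,
                        cyy.normalized_right_response)
        assert np.all(rxx >= ryy)

    def test_degenerate_antisymmetric_point_dropped(self, curves):
        # ε = −1 has zero signed total area and is excluded from the grid
        assert -1.0 not in curves["model_stress"]["sigma_yy"].epsilon_grid


class TestEstimateCoupling:

    def test_inversion_identity_on_grid_point(self, yy_curve):
        curve = yy_curve
        i = list(curve.epsilon_grid).index(0.25)
        est = asim.estimate_coupling(
            curve, response=curve.normalized_right_response[i])
        assert np.isclose(est.epsilon_hat, 0.25, atol=1e-12)

    def test_out_of_range_clamped_and_flagged(self, yy_curve):
        curve = yy_curve
        est = asim.estimate_coupling(curve, response=5.0)
        assert est.extrapolated and est.epsilon_hat == curve.epsilon_grid.max()

    def test_non_monotone_curve_refused(self):
        from mechprop.fields import CouplingCurve
        bad = CouplingCurve(np.array([-1, 0, 1.0]),
                            np.array([0.2, 0.5, 0.3]))
        with pytest.raises(ValueError):
            asim.estimate_coupling(bad, response=0.4)


class TestAttenuationDistance:
    def test_exponential_closed_form(self):
        x = np.linspace(0, 200, 4001)
        x0 = 17.0
        res = asim.attenuation_distance(np.exp(-x / x0), x, fraction=0.2)
        assert abs(res.d_um / (x0 * np.log(5)) - 1) < 0.01

    def test_linear_ramp(self):
        x = np.linspace(0, 50, 501)
        prof = 1 - x / 50.0
        res = asim.attenuation_distance(prof, x, fraction=0.2)
        assert np.isclose(res.d_um, 0.8 * 50.0, rtol=1e-3)

    def test_noisy_profile_matches_brute_force_scan(self):
        rng = np.random.default_rng(3)
        x = np.linspace(0, 60, 200)
        prof = np.exp(-x / 12) + 0.01 * rng.normal(size=200)
        res = asim.attenuation_distance(prof, x, fraction=0.2)
        i_max = int(np.argmax(prof))
        target = 0.2 * prof[i_max]
        brute = None
        for i in range(i_max, 200):
            if prof[i] < target:
                brute = (i - 1, i)
                break
        assert brute is not None
        lo, hi = x[brute[0]], x[brute[1]]
        assert lo - x[i_max] <= res.d_um <= hi - x[i_max]

    def test_never_crossing_flagged_beyond_domain(self):
        res = asim.attenuation_distance(np.ones(50), fraction=0.2)
        assert res.beyond_domain

    def test_monotone_in_epsilon_where_defined(self):
        """Stronger active coupling carries the stress change further."""
        p = asim.FemParams(n_frames=24, activation_window=(12, 22),
                           mesh_resolution_um=2.5)
        ds = []
        for eps in (-0.5, -0.25, 0.0):
            out = asim.simulate_fem(p, epsilon=eps, width_um=45,
                                    height_um=45)
            tb = pl.frame_average(out["traction"], range(9, 12))
            ta = pl.frame_average(out["traction"], range(19, 22))
            sb = msm.msm_solve(tb, np.ones(tb.shape, bool))
            sa = msm.msm_solve(ta, np.ones(ta.shape, bool))
            prof = msm.y_averaged_profiles(msm.stress_difference_map(sb, sa))
            ok = np.isfinite(prof["syy"])
            res = asim.attenuation_distance(prof["syy"][ok],
                                            prof["x_um"][ok])
            assert not res.beyond_domain
            ds.append(res.d_um)
        assert ds[0] < ds[1] < ds[2]
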