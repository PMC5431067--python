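"""Tait EOS fitting and the three γ estimators."""

import numpy as np
import pandas as pd
import pytest

import glassdyn as gd
from glassdyn.eos import TaitEOS
from glassdyn.scaling import collapse_dispersion

TAIT_TRUE = gd.TaitParams(v0=0.80, alpha_v=7e-4, T0=300.0, k=0.0894,
                          b1=800.0, b3=4.5e-3)


class TestTait:
    def test_hand_evaluated_example(self):
        assert gd.specific_volume(TAIT_TRUE, 320.0, 0.0) == pytest.approx(
            0.8112, abs=1e-4)

    def test_zero_pressure_limit_independent_of_compression_params(self):
        other = gd.TaitParams(v0=0.80, alpha_v=7e-4, T0=300.0, k=0.02,
                              b1=50.0, b3=1e-3)
        T = np.linspace(250.0, 370.0, 7)
        np.testing.assert_allclose(gd.specific_volume(TAIT_TRUE, T, 0.0),
                                   gd.specific_volume(other, T, 0.0))

    def test_monotonicity(self):
        P = np.linspace(0.0, 500.0, 30)
        v = gd.specific_volume(TAIT_TRUE, 300.0, P)
        assert np.all(np.diff(v) < 0)
        T = np.linspace(240.0, 370.0, 30)
        vT = gd.specific_volume(TAIT_TRUE, T, 200.0)
        assert np.all(np.diff(vT) > 0)

    def test_parameter_recovery_from_noisy_pvt(self):
        pvt = gd.generate_pvt(TAIT_TRUE, noise=1e-3, seed=1)
        fit = TaitEOS(T0=300.0).fit(pvt[["T_K", "P_MPa"]].to_numpy(),
                                    pvt["v_cm3g"].to_numpy())
        assert fit.v0_ == pytest.approx(0.80, rel=0.01)
        assert fit.alpha_v_ == pytest.approx(7e-4, rel=0.05)
        assert fit.rms_ < 0.005 * 0.8
        # the fitted surface matches the true one across the window
        T = np.linspace(300.0, 370.0, 5)[:, None] + np.zeros((1, 5))
        P = np.linspace(0.0, 300.0, 5)[None, :] + np.zeros((5, 1))
        np.testing.assert_allclose(
            gd.specific_volume(fit.params_, T.ravel(), P.ravel()),
            gd.specific_volume(TAIT_TRUE, T.ravel(), P.ravel()), rtol=2e-3)

    def test_noiseless_recovery_to_solver_tolerance(self):
        pvt = gd.generate_pvt(TAIT_TRUE, noise=0.0)
        fit = gd.fit_tait(pvt, T0=300.0)
        assert fit.v0 == pytest.approx(0.80, rel=1e-6)
        assert fit.k == pytest.approx(0.0894, rel=1e-4)
        assert fit.b1 == pytest.approx(800.0, rel=1e-3)

    def test_single_isotherm_unidentifiable(self):
        pvt = gd.generate_pvt(TAIT_TRUE, isotherms=(330.0,), noise=0.0)
        with pytest.raises(ValueError, match="b3"):
            gd.fit_tait(pvt)

    def test_log_argument_domain_error(self):
        with pytest.raises(ValueError):
            gd.specific_volume(TAIT_TRUE, 300.0, -1e4)


class TestScalingVariable:
    def test_arithmetic(self):
        assert gd.scaling_variable(250.0, 0.8, 2.0) == pytest.approx(6.25)

    def test_gamma_zero_is_pure_temperature(self):
        assert gd.scaling_variable(400.0, 0.73, 0.0) == pytest.approx(2.5)

    def test_invariance(self):
        c = 1.7
        x1 = gd.scaling_variable(300.0, 0.8, 2.0)
        x2 = gd.scaling_variable(300.0 / c, 0.8 * np.sqrt(c), 2.0)
        assert x1 == pytest.approx(x2, rel=1e-12)


def _linear_master_points(gamma=2.0, A=-12.0, B=2.0):
    """Two paths whose Log τ is exactly linear in x = 1000/(T·v^γ)."""
    rows = []
    for P in (0.1, 400.0):
        for T in np.linspace(240.0, 320.0, 15):
            v = gd.specific_volume(TAIT_TRUE, T, P)
            x = gd.scaling_variable(T, v, gamma)
            rows.append({"process": "alpha", "T_K": T, "P_MPa": P,
                         "tau_s": 10.0 ** (A + B * x)})
    return pd.DataFrame(rows)


class TestMasterCurveGamma:
    def test_exact_linear_construction(self):
        pts = _linear_master_points(gamma=2.0)
        res = gd.gamma_master_curve(pts, TAIT_TRUE, tau_max=1e12)
        assert res.gamma == pytest.approx(2.0, abs=0.01)
        assert res.dispersion < 1e-3
        assert res.method == "master_curve"

    def test_dispersion_minimum_at_true_gamma(self):
        pts = _linear_master_points(gamma=2.0)
        d_true = collapse_dispersion(pts, TAIT_TRUE, 2.0, tau_max=1e12)
        for off in (-0.5, 0.5):
            assert collapse_dispersion(pts, TAIT_TRUE, 2.0 + off,
                                       tau_max=1e12) > d_true * 10

    def test_single_path_unidentifiable(self):
        pts = _linear_master_points()
        one = pts[pts.P_MPa == 0.1]
        with pytest.raises(ValueError, match="unidentifiable"):
            gd.gamma_master_curve(one, TAIT_TRUE, tau_max=1e12)

    def test_recovery_on_default_dataset(self, relax_map, tait_fit, truth):
        res = gd.gamma_master_curve(relax_map, tait_fit)
        assert res.gamma == pytest.approx(truth.gamma_true, abs=0.1)

    def test_estimator_interface(self, relax_map, tait_fit):
        from glassdyn.scaling import MasterCurveScaler
        alpha = relax_map[(relax_map.process == "alpha")
                          & (relax_map.tau_s <= 100.0)]
        T = alpha.T_K.to_numpy()
        v = gd.specific_volume(tait_fit, T, alpha.P_MPa.to_numpy())
        scaler = MasterCurveScaler().fit(np.column_stack([T, v]),
                                         np.log10(alpha.tau_s.to_numpy()))
        assert scaler.gamma_ == pytest.approx(2.0, abs=0.1)
        assert scaler.get_params()["gamma_step"] == 0.1


class TestIsochronalGamma:
    def test_constructed_isochrones_give_exact_slope(self):
        # data built so that T·v² is constant along isochrones: γ = 2 exactly
        pts = _linear_master_points(gamma=2.0)
        fits = []
        for P in (0.1, 200.0, 400.0):
            sel = np.linspace(240.0, 320.0, 15)
            tau = np.array([
                10.0 ** (-12.0 + 2.0 * gd.scaling_variable(
                    T, gd.specific_volume(TAIT_TRUE, T, P), 2.0))
                for T in sel])
            fits.append((P, gd.fit_vft(sel, tau, tau_max=None)))
        res = gd.gamma_isochronal_slope(fits, TAIT_TRUE,
                                        tau_list=(1e-4, 1e-2, 1.0))
        assert res.gamma == pytest.approx(2.0, abs=0.05)

    def test_two_isobars_single_tau_is_exact_two_point_slope(self):
        fits = []
        for P in (0.1, 300.0, 600.0):
            T = np.linspace(240.0, 320.0, 12)
            tau = np.array([
                10.0 ** (-12.0 + 2.0 * gd.scaling_variable(
                    t, gd.specific_volume(TAIT_TRUE, t, P), 2.0))
                for t in T])
            fits.append((P, gd.fit_vft(T, tau, tau_max=None)))
        two = fits[:2] + fits[2:]
        res = gd.gamma_isochronal_slope(two, TAIT_TRUE, tau_list=(1e-2,))
        assert res.se == 0.0
        assert res.gamma == pytest.approx(2.0, abs=0.05)

    def test_needs_three_isobars(self):
        with pytest.raises(ValueError):
            gd.gamma_isochronal_slope([(0.1, gd.VFTParams(1e-14, 10, 180))],
                                      TAIT_TRUE)

    def test_recovery_and_cross_method_agreement(self, relax_map, tait_fit,
                                                 isobar_vft_fits, truth):
        iso = gd.gamma_isochronal_slope(isobar_vft_fits, tait_fit)
        assert iso.gamma == pytest.approx(truth.gamma_true, abs=0.15)
        mc = gd.gamma_master_curve(relax_map, tait_fit)
        assert abs(iso.gamma - mc.gamma) <= np.hypot(iso.se, mc.se) + 0.1


class TestThermodynamicGamma:
    def test_reported_static_quantity_value(self):
        res = gd.gamma_thermodynamic(gd.default_thermo_quantities())
        assert res.gamma == pytest.approx(2.0, abs=0.05)

    def test_unit_identity(self):
        # ΔC_P·κ_T/(Δα_P·V_g) = 1 and α_P → 0 gives γ = 1
        tq = gd.ThermoQuantities(alpha_P=1e-12, d_alpha_P=1e-3, d_Cp=100.0,
                                 kappa_T=1e-3, V_g=100.0, Tg=230.0)
        assert gd.gamma_thermodynamic(tq).gamma == pytest.approx(1.0, rel=1e-6)

    def test_monotone_in_first_term(self):
        base = gd.default_thermo_quantities()
        bigger = gd.ThermoQuantities(alpha_P=base.alpha_P,
                                     d_alpha_P=base.d_alpha_P,
                                     d_Cp=2 * base.d_Cp,
                                     kappa_T=2 * base.kappa_T,
                                     V_g=base.V_g, Tg=base.Tg)
        assert gd.gamma_thermodynamic(bigger).gamma < \
            gd.gamma_thermodynamic(base).gamma

    def test_negative_denominator_reported(self):
        tq = gd.ThermoQuantities(alpha_P=1e-2, d_alpha_P=1e-3, d_Cp=100.0,
                                 kappa_T=1e-3, V_g=100.0, Tg=300.0)
        with pytest.raises(ValueError, match="denominator"):
            gd.gamma_thermodynamic(tq)

    def test_error_propagation(self):
        res = gd.gamma_thermodynamic(
            gd.default_thermo_quantities(),
            uncertainties={"d_Cp": 5.0, "kappa_T": 2e-5})
        assert res.se > 0
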