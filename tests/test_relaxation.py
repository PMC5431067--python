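"""VFT, fragility, pressure-Arrhenius, Andersson-Andersson and the β kink."""

import numpy as np
import pytest

import glassdyn as gd
from glassdyn.relaxation import (
    VFTRegressor,
    andersson_tg,
    eval_pressure_arrhenius,
    eval_vft,
)

VFT_FIXTURE = gd.VFTParams(tau_inf=1e-14, s=10.62, T_VF=180.0)


class TestVFT:
    def test_exact_recovery(self):
        T = np.linspace(235.0, 290.0, 12)
        tau = eval_vft(VFT_FIXTURE, T)
        fit = gd.fit_vft(T, tau, tau_max=None)
        assert fit.tau_inf == pytest.approx(1e-14, rel=1e-4)
        assert fit.s == pytest.approx(10.62, rel=1e-5)
        assert fit.T_VF == pytest.approx(180.0, rel=1e-5)

    def test_value_at_twice_tvf(self):
        # τ(2·T_VF) = τ∞ · e^s, an algebraic identity of the VFT form
        assert eval_vft(VFT_FIXTURE, 360.0) == pytest.approx(
            1e-14 * np.exp(10.62), rel=1e-12)

    def test_noisy_recovery_within_ten_percent(self):
        rng = np.random.default_rng(5)
        T = np.linspace(234.0, 300.0, 20)
        lt = np.log10(eval_vft(VFT_FIXTURE, T))
        lt_noisy = lt + 0.05 * rng.standard_normal(lt.size)
        fit = gd.fit_vft(T, 10.0 ** lt_noisy, tau_max=None)
        assert fit.s == pytest.approx(10.62, rel=0.10)
        assert fit.T_VF == pytest.approx(180.0, rel=0.10)

    def test_supercooled_filter_excludes_glassy_points(self):
        T = np.linspace(228.0, 290.0, 20)
        tau = eval_vft(VFT_FIXTURE, T)
        reg = VFTRegressor(tau_max=100.0).fit(T, tau)
        assert reg.params_.T_VF == pytest.approx(180.0, rel=1e-4)

    def test_insufficient_span_raises(self):
        T = np.array([280.0, 281.0, 282.0, 283.0, 284.0])
        with pytest.raises(ValueError):
            gd.fit_vft(T, eval_vft(VFT_FIXTURE, T), tau_max=None)


class TestGlassTransitionTemperature:
    def test_closed_form_value(self):
        assert gd.glass_transition_temperature(VFT_FIXTURE) == pytest.approx(
            231.9, abs=0.05)

    def test_round_trip(self):
        Tg = gd.glass_transition_temperature(VFT_FIXTURE)
        assert eval_vft(VFT_FIXTURE, Tg) == pytest.approx(100.0, rel=1e-10)

    def test_monotone_in_strength(self):
        tgs = [gd.glass_transition_temperature(
            gd.VFTParams(1e-14, s, 180.0)) for s in (8.0, 10.0, 12.0)]
        assert tgs == sorted(tgs)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            gd.glass_transition_temperature(gd.VFTParams(1.0, 10.0, 180.0),
                                            tau_g=0.5)


class TestFragility:
    def test_closed_form_vs_numerical_derivative(self):
        Tg = gd.glass_transition_temperature(VFT_FIXTURE)
        m = gd.fragility(VFT_FIXTURE, Tg)
        assert m == pytest.approx(71.5, abs=0.1)
        # central difference of Log τ with respect to Tg/T at T = Tg
        h = 1e-6
        x = Tg / np.array([Tg / (1 + h), Tg / (1 - h)])
        lt = np.log10(eval_vft(VFT_FIXTURE, Tg / x))
        m_num = (lt[0] - lt[1]) / (2 * h)
        assert m == pytest.approx(m_num, rel=1e-6)

    def test_strong_glass_limit(self):
        # T_VF → 0 with s·T_VF fixed: m → Log(τ_g/τ∞) = 16
        vft = gd.VFTParams(1e-14, 2e6, 1e-3)
        Tg = gd.glass_transition_temperature(vft)
        assert gd.fragility(vft, Tg) == pytest.approx(16.0, rel=1e-3)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            gd.fragility(VFT_FIXTURE, Tg=170.0)


class TestPressureArrhenius:
    FIXTURE = gd.ArrheniusPParams(tau_0=9.2e-5, V_a=101.5, T=260.0)

    def test_exact_recovery(self):
        P = np.linspace(0.0, 300.0, 8)
        tau = eval_pressure_arrhenius(self.FIXTURE, P)
        fit = gd.fit_pressure_arrhenius(P, tau, T=260.0)
        assert fit.tau_0 == pytest.approx(9.2e-5, rel=1e-10)
        assert fit.V_a == pytest.approx(101.5, rel=1e-10)

    def test_glass_transition_pressure(self):
        assert gd.glass_transition_pressure(self.FIXTURE) == pytest.approx(
            296.0, abs=1.0)

    def test_pg_round_trip(self):
        Pg = gd.glass_transition_pressure(self.FIXTURE)
        assert eval_pressure_arrhenius(self.FIXTURE, Pg) == pytest.approx(
            100.0, rel=1e-10)

    def test_scale_invariance(self):
        P = np.linspace(0.0, 400.0, 5)
        halved = gd.ArrheniusPParams(tau_0=9.2e-5, V_a=101.5 / 2, T=260.0)
        np.testing.assert_allclose(
            eval_pressure_arrhenius(self.FIXTURE, P),
            eval_pressure_arrhenius(halved, 2 * P), rtol=1e-12)

    def test_activation_volume_decreases_with_temperature(self, relax_map):
        """The fixture's four isotherms reproduce the decreasing V_a trend."""
        alpha = relax_map[(relax_map.process == "alpha")
                          & (relax_map.tau_s <= 100.0)]
        vas = []
        for T in (260.0, 280.0, 300.0, 320.0):
            g = alpha[alpha.T_K == T]
            vas.append(gd.fit_pressure_arrhenius(g.P_MPa, g.tau_s, T=T).V_a)
        assert all(a > b for a, b in zip(vas, vas[1:]))

    def test_pg_increases_with_temperature(self, relax_map):
        alpha = relax_map[(relax_map.process == "alpha")
                          & (relax_map.tau_s <= 100.0)]
        pgs = []
        for T in (260.0, 280.0, 300.0, 320.0):
            g = alpha[alpha.T_K == T]
            arr = gd.fit_pressure_arrhenius(g.P_MPa, g.tau_s, T=T)
            pgs.append(gd.glass_transition_pressure(arr))
        assert all(a < b for a, b in zip(pgs, pgs[1:]))

    def test_short_pressure_span_raises(self):
        P = np.array([0.0, 20.0, 40.0, 60.0])
        with pytest.raises(ValueError):
            gd.fit_pressure_arrhenius(
                P, eval_pressure_arrhenius(self.FIXTURE, P), T=260.0)


class TestAndersson:
    TG_PAIRS = ([1e-4, 0.225, 0.4, 0.6], [231.9, 251.2, 270.8, 284.0])

    def test_ambient_intercept(self):
        params = gd.AnderssonParams(k1=230.0, k2=1.2, k3=0.4)
        assert andersson_tg(params, 0.0) == 230.0

    def test_reported_tg_pressure_cross_consistency(self):
        # fitting the four isobaric Tg values and evaluating at the 260 K
        # glass-transition pressure must land near 260 K
        fit = gd.fit_andersson(*self.TG_PAIRS)
        assert andersson_tg(fit, 0.296) == pytest.approx(260.0, abs=5.0)

    def test_exact_model_recovery(self):
        true = gd.AnderssonParams(k1=231.9, k2=1.8, k3=0.35)
        P = np.array([0.0, 0.1, 0.25, 0.4, 0.6, 0.8])
        fit = gd.fit_andersson(P, andersson_tg(true, P))
        assert fit.k1 == pytest.approx(true.k1, rel=1e-6)
        assert fit.k2 == pytest.approx(true.k2, rel=1e-4)
        assert fit.k3 == pytest.approx(true.k3, rel=1e-4)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            gd.fit_andersson([0.0, 0.2, 0.4], [230.0, 250.0, 265.0])


class TestCrossover:
    def _kinked(self, Tb=231.9, E_liq=14000.0, ratio=0.5, noise=0.0, seed=0):
        T = np.arange(Tb - 24.0, Tb + 26.0, 2.0)
        x = 1.0 / T
        xb = 1.0 / Tb
        lnf = np.where(x > xb, ratio * E_liq * (x - xb), E_liq * (x - xb))
        y = -8.0 * np.log(10) + lnf
        if noise:
            y = y + noise * np.random.default_rng(seed).standard_normal(y.size)
        return T, np.exp(y)

    def test_kink_detected_near_truth(self):
        T, tau = self._kinked(noise=0.05, seed=2)
        cx = gd.detect_crossover(T, tau, seed=0)
        assert cx is not None
        assert cx.T_break == pytest.approx(231.9, abs=5.0)

    def test_glass_side_slope_is_weaker(self):
        T, tau = self._kinked(noise=0.05, seed=4)
        cx = gd.detect_crossover(T, tau, seed=0)
        assert cx.slope_below < cx.slope_above

    def test_single_slope_gives_null(self):
        T = np.arange(210.0, 260.0, 2.0)
        tau = np.exp(-20.0 + 5000.0 / T
                     + 0.05 * np.random.default_rng(9).standard_normal(T.size))
        assert gd.detect_crossover(T, tau, seed=0) is None

    def test_fixture_beta_kink_at_tg(self, relax_map, truth):
        beta = relax_map[(relax_map.process == "beta")
                         & (relax_map.P_MPa == 0.1)]
        cx = gd.detect_crossover(beta.T_K, beta.tau_s, seed=1)
        assert cx is not None
        assert cx.T_break == pytest.approx(truth.tg_of_pressure(0.1), abs=5.0)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            gd.detect_crossover([250.0, 252.0, 254.0], [1.0, 0.5, 0.2])


class TestChainConsistency:
    def test_isobaric_vs_isothermal_glass_lines_agree(self, relax_map):
        """Tg(P) interpolated from isobars matches the (Pg, T) points from
        isothermal fits within the experimental spread (5 K)."""
        alpha = relax_map[(relax_map.process == "alpha")
                          & (relax_map.tau_s <= 100.0)]
        tg_points = []
        for P in (0.1, 200.0, 400.0, 600.0):
            g = alpha[alpha.P_MPa == P]
            vft = gd.fit_vft(g.T_K, g.tau_s)
            tg_points.append((P / 1000.0, gd.glass_transition_temperature(vft)))
        andersson = gd.fit_andersson(*zip(*tg_points))
        for T in (260.0, 280.0):
            g = alpha[alpha.T_K == T]
            arr = gd.fit_pressure_arrhenius(g.P_MPa, g.tau_s, T=T)
            Pg = gd.glass_transition_pressure(arr)
            assert andersson_tg(andersson, Pg / 1000.0) == pytest.approx(
                T, abs=5.0)
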