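"""Unit tests for the model right-hand sides (no integration of the full set)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from nichesim.params import (ModelParams, ModelState, PacemakerParams,
                             PhoticParams, RelayMaskingParams,
                             SleepSwitchParams, HomeostatParams)
from nichesim.model import (firing_rate, homeostat_rhs, relay_drive,
                            masking_drive, masking_signal, photic_alpha,
                            photoreceptor_rhs, circadian_light_drive,
                            nonphotic_drive, pacemaker_rhs, full_rhs)
from nichesim.protocols import LightSchedule


class TestFiringRate:
    def test_midpoint_and_saturation(self, default_params):
        sw = default_params.switch
        assert firing_rate(sw.theta, sw) == pytest.approx(sw.Q_max / 2)
        assert firing_rate(-1e6, sw) == pytest.approx(0.0, abs=1e-12)
        assert firing_rate(1e6, sw) == pytest.approx(sw.Q_max)

    def test_three_quarter_point(self, default_params):
        # closed form: Q(theta + sigma*ln 3) = Q_max/(1 + 1/3) = 0.75 Q_max
        sw = default_params.switch
        V = sw.theta + sw.sigma * math.log(3.0)
        assert firing_rate(V, sw) == pytest.approx(0.75 * sw.Q_max, rel=1e-12)

    def test_nonfinite_voltage_rejected(self, default_params):
        for bad in (float("nan"), float("inf"), -float("inf")):
            with pytest.raises(ValueError):
                firing_rate(bad, default_params.switch)

    @given(v1=st.floats(-500, 500), dv=st.floats(1e-6, 100))
    @settings(max_examples=200, deadline=None)
    def test_strictly_increasing_and_bounded(self, v1, dv):
        sw = SleepSwitchParams()
        q1, q2 = firing_rate(v1, sw), firing_rate(v1 + dv, sw)
        assert 0.0 < q2 <= sw.Q_max
        assert q2 > q1 or q2 == pytest.approx(sw.Q_max)


class TestHomeostat:
    def test_exponential_decay_solution(self):
        p = HomeostatParams(chi=2.0, mu=4.4)
        chi_s = p.chi * 3600.0
        H0 = 12.0
        sol = solve_ivp(lambda t, y: [homeostat_rhs(y[0], 0.0, p)],
                        (0, 3 * chi_s), [H0], rtol=1e-10, atol=1e-12)
        assert sol.y[0, -1] == pytest.approx(H0 * math.exp(-3.0), rel=1e-6)

    def test_fixed_point(self):
        p = HomeostatParams(chi=10.0, mu=4.4)
        Q = 5.0
        assert homeostat_rhs(p.mu * Q, Q, p) == pytest.approx(0.0, abs=1e-15)

    def test_nonpositive_chi_rejected(self):
        with pytest.raises(ValueError):
            homeostat_rhs(1.0, 1.0, HomeostatParams(chi=-1.0, mu=1.0))


class TestRelayDrive:
    def test_nu_zero_gives_constant_drives(self):
        rl = RelayMaskingParams(nu_spz=0.0, c_offset=0.7, g_dmh_vlpo=3.0,
                                g_dmh_lha=1.0)
        drives = {relay_drive(ModelState(x=x), rl) for x in (-1.0, 0.0, 1.0)}
        assert drives == {(-3.0 * 0.7, 1.0 * 0.7)}

    def test_lesion_removes_pacemaker_dependence(self):
        rl = RelayMaskingParams(nu_spz=1.0, c_offset=0.7, g_dmh_vlpo=3.0,
                                scn_gain=0.0)
        d1 = relay_drive(ModelState(x=-1.0, x_c=0.5), rl)
        d2 = relay_drive(ModelState(x=1.0, x_c=-0.5), rl)
        assert d1 == d2

    def test_mirror_symmetry_about_nu_zero(self):
        state = ModelState(x=0.37)
        mk = lambda nu: RelayMaskingParams(nu_spz=nu, c_offset=0.5,
                                           g_dmh_vlpo=2.0, g_dmh_lha=1.0)
        d0 = np.array(relay_drive(state, mk(0.0)))
        dp = np.array(relay_drive(state, mk(0.6)))
        dm = np.array(relay_drive(state, mk(-0.6)))
        np.testing.assert_allclose(dp - d0, -(dm - d0), rtol=1e-12)

    def test_affine_in_C_with_slope_proportional_to_nu(self):
        # finite differences of the drive w.r.t. x are constant (affine) and
        # scale linearly with nu_spz
        xs = np.linspace(-1, 1, 7)
        for nu in (0.25, 0.5, 1.0):
            rl = RelayMaskingParams(nu_spz=nu, c_offset=0.3, g_dmh_vlpo=2.0)
            d = np.array([relay_drive(ModelState(x=x), rl)[0] for x in xs])
            slopes = np.diff(d) / np.diff(xs)
            np.testing.assert_allclose(slopes, slopes[0], rtol=1e-12)
            assert slopes[0] == pytest.approx(-2.0 * nu * 0.5, rel=1e-12)


class TestMasking:
    def test_darkness_produces_no_masking(self, default_params):
        ph = default_params.photic
        for m in (-3.0, 0.0, 3.0):
            rl = RelayMaskingParams(m_mask=m)
            assert masking_drive(0.0, rl, ph) == 0.0

    def test_sign_convention(self, default_params):
        ph = default_params.photic
        pos = masking_drive(100.0, RelayMaskingParams(m_mask=2.0), ph)
        neg = masking_drive(100.0, RelayMaskingParams(m_mask=-2.0), ph)
        assert pos > 0  # excitatory, sleep-promoting = negative masking
        assert neg == pytest.approx(-pos, rel=1e-12)  # exact linearity in gain

    @pytest.mark.parametrize("mode", ["photoreceptor", "linear"])
    def test_signal_monotone_with_zero_at_dark(self, mode, default_params):
        rl = RelayMaskingParams(masking_mode=mode)
        lux = [0.0, 10.0, 100.0, 1000.0]
        f = [masking_signal(i, 0.0, rl, default_params.photic) for i in lux]
        assert f[0] == 0.0
        assert all(b > a for a, b in zip(f, f[1:]))

    def test_negative_lux_rejected(self, default_params):
        with pytest.raises(ValueError):
            masking_drive(-1.0, RelayMaskingParams(), default_params.photic)


class TestPhotoreception:
    def test_alpha_zero_in_darkness_and_monotone(self, default_params):
        ph = default_params.photic
        assert photic_alpha(0.0, ph) == 0.0
        assert photic_alpha(100.0, ph) > photic_alpha(30.0, ph) > 0.0

    def test_alpha_closed_form_at_reference(self, default_params):
        # direct substitution: alpha(I_0) = alpha_0 * I_0/(I_0 + I_1)
        ph = default_params.photic
        expected = ph.alpha_0 * ph.I_0 / (ph.I_0 + ph.I_1)
        assert photic_alpha(ph.I_0, ph) == pytest.approx(expected, rel=1e-12)

    def test_negative_irradiance_rejected(self, default_params):
        with pytest.raises(ValueError):
            photic_alpha(-5.0, default_params.photic)

    def test_equilibrium_fraction(self, default_params):
        ph = default_params.photic
        alpha = photic_alpha(200.0, ph)
        nstar = alpha / (alpha + ph.beta)
        assert photoreceptor_rhs(nstar, alpha, ph) == pytest.approx(0.0, abs=1e-18)

    def test_dark_recovery_and_step_response(self, default_params):
        ph = default_params.photic
        # dark: n decays exponentially at rate beta
        sol = solve_ivp(lambda t, y: [photoreceptor_rhs(y[0], 0.0, ph)],
                        (0, 2 / ph.beta), [0.8], rtol=1e-10, atol=1e-12)
        assert sol.y[0, -1] == pytest.approx(0.8 * math.exp(-2.0), rel=1e-6)
        # light step from darkness: relaxation to n* at rate alpha + beta
        alpha = photic_alpha(500.0, ph)
        tau = 1.0 / (alpha + ph.beta)
        nstar = alpha / (alpha + ph.beta)
        sol = solve_ivp(lambda t, y: [photoreceptor_rhs(y[0], alpha, ph)],
                        (0, tau), [0.0], rtol=1e-10, atol=1e-12)
        assert sol.y[0, -1] == pytest.approx(nstar * (1 - math.exp(-1)), rel=1e-6)

    def test_fraction_out_of_bounds_rejected(self, default_params):
        with pytest.raises(ValueError):
            photoreceptor_rhs(1.2, 0.0, default_params.photic)


class TestCircadianLightDrive:
    def test_zeros(self, default_params):
        ph = default_params.photic
        st_ = ModelState(x=0.1, x_c=-0.2, n=0.3)
        assert circadian_light_drive(st_, True, 0.0, ph) == 0.0
        # eye closure gates all light during sleep
        assert circadian_light_drive(st_, False, 1e4, ph) == 0.0
        # fully activated photoreceptor pool transduces nothing
        st_.n = 1.0
        assert circadian_light_drive(st_, True, 500.0, ph) == pytest.approx(0.0)


class TestNonphoticDrive:
    def test_zero_strength(self):
        p = PacemakerParams(rho_np=0.0)
        st_ = ModelState(x=0.2)
        assert nonphotic_drive(True, st_, p) == 0.0
        assert nonphotic_drive(False, st_, p) == 0.0

    def test_two_level_switch(self):
        p = PacemakerParams()
        st_ = ModelState(x=-0.4, x_c=0.9)
        nw = nonphotic_drive(True, st_, p)
        ns = nonphotic_drive(False, st_, p)
        assert nw != ns
        assert {nonphotic_drive(a, st_, p) for a in (True, False)} == {nw, ns}


class TestPacemaker:
    @pytest.mark.parametrize("tau_c", [23.0, 24.2, 25.2])
    def test_unforced_period_matches_tau_c(self, tau_c):
        p = PacemakerParams(tau_c=tau_c)

        def rhs(t, y):
            return pacemaker_rhs(ModelState(x=y[0], x_c=y[1]), 0.0, 0.0, p)

        t_end = 30 * 25 * 3600.0
        sol = solve_ivp(rhs, (0, t_end), [1.0, 0.0], rtol=1e-9, atol=1e-9,
                        dense_output=True)
        t = np.linspace(t_end - 15 * 25 * 3600, t_end, 200000)
        x = sol.sol(t)[0]
        ups = np.flatnonzero((x[:-1] < 0) & (x[1:] >= 0))
        periods = np.diff(t[ups]) / 3600.0
        assert np.mean(periods) == pytest.approx(tau_c, rel=0.01)


class TestFullRhs:
    def test_decoupled_voltages_relax_to_drive(self):
        # with vanishing couplings and drives the voltages decay linearly
        p = ModelParams(
            switch=SleepSwitchParams(nu_vm=-1e-9, nu_mv=-1e-9, nu_vh=0.0,
                                     A_m=0.0),
            relay=RelayMaskingParams(nu_spz=0.0, c_offset=0.0, g_dmh_vlpo=0.0),
        )
        st_ = ModelState(V_v=5.0, V_m=-3.0, H=0.0, x=0.0, x_c=0.0, n=0.0)
        dy = full_rhs(st_, 0.0, p, LightSchedule.dd())
        assert dy[0] == pytest.approx(-5.0 / p.switch.tau_v, rel=1e-6)
        assert dy[1] == pytest.approx(3.0 / p.switch.tau_m, rel=1e-4)

    def test_compositional_consistency(self, default_params, rng):
        """The composed derivative equals the independently assembled
        subsystem derivatives at random states."""
        p = default_params
        p.relay = RelayMaskingParams(nu_spz=0.6, c_offset=0.4, g_dmh_vlpo=3.0,
                                     g_dmh_lha=-0.8, m_mask=-2.0)
        sched = LightSchedule.ld(8, 20, 150.0)
        for _ in range(10):
            st_ = ModelState(V_v=rng.uniform(-15, 5), V_m=rng.uniform(-15, 5),
                             H=rng.uniform(0, 20), x=rng.uniform(-1.1, 1.1),
                             x_c=rng.uniform(-1.1, 1.1), n=rng.uniform(0, 1))
            t = rng.uniform(0, 86400)
            dy = full_rhs(st_, t, p, sched)
            sw, ph = p.switch, p.photic
            Q_v = firing_rate(st_.V_v, sw)
            Q_m = firing_rate(st_.V_m, sw)
            awake = Q_m > p.wake_threshold
            I = sched.lux_at(t)
            I_eff = I if awake else ph.eye_closure_factor * I
            d_rel_v, d_rel_m = relay_drive(st_, p.relay, p)
            D_v = sw.nu_vh * st_.H + d_rel_v + masking_drive(I_eff, p.relay,
                                                             ph, st_.n)
            D_m = sw.A_m + d_rel_m
            assert dy[0] == pytest.approx(
                (sw.nu_vm * Q_m + D_v - st_.V_v) / sw.tau_v, rel=1e-12)
            assert dy[1] == pytest.approx(
                (sw.nu_mv * Q_v + D_m - st_.V_m) / sw.tau_m, rel=1e-12)
            assert dy[2] == pytest.approx(
                homeostat_rhs(st_.H, Q_m, p.homeostat), rel=1e-12)
            B = circadian_light_drive(st_, awake, I, ph)
            N = nonphotic_drive(awake, st_, p.pacemaker)
            dx, dxc = pacemaker_rhs(st_, B, N, p.pacemaker)
            assert dy[3] == pytest.approx(dx, rel=1e-12)
            assert dy[4] == pytest.approx(dxc, rel=1e-12)
            assert dy[5] == pytest.approx(
                photoreceptor_rhs(st_.n, photic_alpha(I_eff, ph), ph), rel=1e-12)

    def test_switch_bistability_for_some_drive(self):
        """With constant drives and the homeostat frozen, the deterministic
        flip-flop admits coexisting high-Q_m and low-Q_m states somewhere
        in the drive range."""
        sw = SleepSwitchParams()

        def settle(D_v, V0):
            def rhs(t, y):
                Qv, Qm = (firing_rate(y[0], sw), firing_rate(y[1], sw))
                return [(sw.nu_vm * Qm + D_v - y[0]) / sw.tau_v,
                        (sw.nu_mv * Qv + sw.A_m - y[1]) / sw.tau_m]
            sol = solve_ivp(rhs, (0, 600), V0, rtol=1e-8)
            return firing_rate(sol.y[1, -1], sw)

        bistable = []
        for D_v in np.linspace(0.0, 12.0, 25):
            q_wake = settle(D_v, [-12.0, 2.0])   # start wake-like
            q_sleep = settle(D_v, [8.0, -12.0])  # start sleep-like
            bistable.append(q_wake > 1.0 > q_sleep)
        assert any(bistable)
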