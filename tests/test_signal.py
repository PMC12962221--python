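"""Signal-model tests: lineshape, saturation rates, Bloch-Siegert phase,
closed-form steady state vs the propagation oracle, and the Jacobian."""

import numpy as np
import pytest

from qmtrecon.signal import (
    AcquisitionProtocol,
    ConvergenceError,
    FixedPoolConstants,
    InvalidParameterError,
    TissueParams,
    bloch_siegert_phase,
    bts_signal,
    bts_signal_series,
    constant_pulse,
    fermi_pulse,
    in_vivo_protocol,
    lineshape_at_zero,
    mean_saturation_rate,
    measurement_constants,
    phantom_protocol,
    signal_jacobian,
    signal_magnitude_series,
    simulate_steady_state,
    superlorentzian_lineshape,
)

GAMMA = 2.6752218744e8


def dense_lineshape_oracle(delta, t2r, n=1_000_000):
    """Brute-force trapezoid quadrature split at the singular point."""
    u_s = 1.0 / np.sqrt(3.0)

    def integrand(u):
        d = 3.0 * u * u - 1.0
        return (
            np.sqrt(2 / np.pi) * (t2r / np.abs(d)) * np.exp(-2 * (2 * np.pi * delta * t2r / d) ** 2)
        )

    total = 0.0
    for lo, hi in ((0.0, u_s), (u_s, 1.0)):
        # open interval: the endpoint singularity is integrable
        u = np.linspace(lo + 1e-9, hi - 1e-9, n // 2)
        total += np.trapezoid(integrand(u), u)
    return total


class TestLineshape:
    def test_even_in_offset(self):
        assert superlorentzian_lineshape(4000.0, 10e-6) == pytest.approx(
            superlorentzian_lineshape(-4000.0, 10e-6), rel=1e-12
        )

    def test_matches_dense_quadrature_oracle(self):
        val = superlorentzian_lineshape(4000.0, 10e-6)
        oracle = dense_lineshape_oracle(4000.0, 10e-6)
        assert val == pytest.approx(oracle, rel=1e-6)

    def test_decreasing_with_offset(self):
        assert superlorentzian_lineshape(2000.0, 10e-6) > superlorentzian_lineshape(
            8000.0, 10e-6
        )

    def test_positive(self):
        for d in (1000.0, 4000.0, 20000.0):
            assert superlorentzian_lineshape(d, 10e-6) > 0

    def test_invalid_t2r_rejected(self):
        with pytest.raises(InvalidParameterError):
            superlorentzian_lineshape(4000.0, -1e-6)

    def test_on_resonance_extrapolation(self):
        g0 = lineshape_at_zero(10e-6, "extrapolate")
        g1 = superlorentzian_lineshape(1000.0, 10e-6)
        g2 = superlorentzian_lineshape(2000.0, 10e-6)
        assert g0 == pytest.approx(2 * g1 - g2)
        assert lineshape_at_zero(10e-6, "zero") == 0.0


class TestSaturationRate:
    def test_zero_amplitude(self, consts):
        assert mean_saturation_rate(fermi_pulse(b1_max=0.0), 4000.0, consts) == 0.0

    def test_scales_as_b1_squared(self, consts):
        w1 = mean_saturation_rate(fermi_pulse(b1_max=1.0), 4000.0, consts)
        w2 = mean_saturation_rate(fermi_pulse(b1_max=2.0), 4000.0, consts)
        assert w2 == pytest.approx(4.0 * w1, rel=1e-12)

    def test_constant_envelope_closed_form(self, consts):
        pulse = constant_pulse(b1_max=5.0, delta_off=4000.0)
        w = mean_saturation_rate(pulse, 4000.0, consts)
        omega = GAMMA * 5e-6
        expected = np.pi * omega**2 * superlorentzian_lineshape(4000.0, consts.t2r)
        assert w == pytest.approx(expected, rel=1e-12)

    def test_fermi_pulse_trapezoid_oracle(self, consts):
        pulse = fermi_pulse(8e-3, 7.3, 4000.0)
        w = mean_saturation_rate(pulse, 4000.0, consts)
        t = pulse.time_grid
        om = GAMMA * 7.3e-6 * pulse.env
        oracle = (
            np.pi
            * (np.trapezoid(om**2, t) / pulse.tau_bts)
            * superlorentzian_lineshape(4000.0, consts.t2r)
        )
        assert w == pytest.approx(oracle, rel=1e-8)

    def test_nonnegative(self, consts):
        assert mean_saturation_rate(fermi_pulse(), 4000.0, consts) >= 0


class TestBlochSiegertPhase:
    def test_quadratic_in_b1(self):
        p1 = fermi_pulse(b1_max=9.128 / 2)
        p2 = fermi_pulse(b1_max=9.128)
        assert bloch_siegert_phase(p2) == pytest.approx(
            4.0 * bloch_siegert_phase(p1), rel=1e-12
        )

    def test_quadrature_oracle(self):
        pulse = fermi_pulse(8e-3, 9.128, 4000.0)
        phi = bloch_siegert_phase(pulse)
        b1 = 9.128e-6
        integ = np.trapezoid((GAMMA * pulse.env) ** 2, pulse.time_grid)
        oracle = b1 * b1 * integ / (2 * 2 * np.pi * 4000.0)
        assert phi == pytest.approx(oracle, rel=1e-8)

    def test_sign_follows_offset(self):
        up = bloch_siegert_phase(fermi_pulse(delta_off=4000.0))
        dn = bloch_siegert_phase(fermi_pulse(delta_off=-4000.0))
        assert up > 0 > dn
        assert up == pytest.approx(-dn)

    def test_zero_offset_rejected(self):
        with pytest.raises(InvalidParameterError):
            bloch_siegert_phase(fermi_pulse(delta_off=0.0))


class TestClosedForm:
    def test_zero_i0_gives_zero(self, consts, protocol):
        p = TissueParams(0.0, 1.0, 0.1, 2.0)
        assert np.allclose(bts_signal_series(p, consts, protocol), 0.0)

    def test_single_pool_limit_is_spgr(self, consts, protocol):
        p = TissueParams(1.0, 1.3, 0.0, 0.0)
        mc = measurement_constants(protocol, consts)
        e1 = np.exp(-protocol.tr / p.t1f)
        for i, (alpha, sat_on) in enumerate(protocol.measurements):
            if sat_on:
                continue
            a = np.deg2rad(alpha)
            spgr = np.sin(a) * (1 - e1) / (1 - e1 * np.cos(a))
            assert abs(bts_signal(p, consts, protocol, i)) == pytest.approx(spgr, rel=1e-12)

    def test_magnitude_vanishes_with_flip_angle(self, consts):
        prot = AcquisitionProtocol(
            measurements=((1e-5, False), (10.0, False)), tr=40e-3, te=12e-3
        )
        p = TissueParams(1.0, 1.0, 0.1, 2.0)
        s = bts_signal_series(p, consts, prot)
        assert abs(s[0]) < 1e-6

    def test_saturation_reduces_signal_when_f_positive(self, consts, protocol):
        p = TissueParams(1.0, 1.0, 0.15, 3.0)
        s = bts_signal_series(p, consts, protocol)
        sat = protocol.saturation_on
        flips = protocol.flip_angles_deg
        for a in np.unique(flips):
            m_off = np.abs(s)[(flips == a) & ~sat][0]
            m_on = np.abs(s)[(flips == a) & sat][0]
            assert m_on <= m_off

    def test_ernst_angle_behavior(self, consts, protocol):
        # magnitude rises then falls across 5..60 deg for T1F near 1 s
        p = TissueParams(1.0, 1.0, 0.1, 2.0)
        s = np.abs(bts_signal_series(p, consts, protocol))
        off = s[~protocol.saturation_on]
        peak = np.argmax(off)
        assert 0 < peak < len(off) - 1

    def test_series_matches_elementwise_signal(self, consts, protocol, wm_params):
        series = bts_signal_series(wm_params, consts, protocol)
        assert len(series) == protocol.n_measurements
        for i in range(protocol.n_measurements):
            assert series[i] == bts_signal(wm_params, consts, protocol, i)

    def test_out_of_bounds_params_rejected(self):
        with pytest.raises(InvalidParameterError):
            TissueParams(1.0, -0.5, 0.1, 2.0)
        with pytest.raises(InvalidParameterError):
            TissueParams(1.0, 1.0, 1.5, 2.0)

    def test_exchange_rate_conventions_agree(self, wm_params):
        # Ek admits three equivalent forms: k, kF/f, kR/(1-f)
        k = wm_params.k
        assert k == pytest.approx(wm_params.kf / wm_params.f)
        assert k == pytest.approx(wm_params.kr / (1 - wm_params.f))


class TestSteadyStateOracle:
    def test_single_pool_spgr_convergence(self, consts, protocol):
        p = TissueParams(1.0, 1.2, 0.0, 0.0)
        idx = 0  # saturation-off measurement
        s = simulate_steady_state(p, consts, protocol, idx, tol=1e-13)
        e1 = np.exp(-protocol.tr / p.t1f)
        a = np.deg2rad(protocol.measurements[idx][0])
        spgr = np.sin(a) * (1 - e1) / (1 - e1 * np.cos(a))
        assert abs(s) == pytest.approx(spgr, rel=1e-10)

    def test_closed_form_agreement(self, consts, protocol, wm_params):
        for i in range(protocol.n_measurements):
            cf = bts_signal(wm_params, consts, protocol, i)
            orc = simulate_steady_state(wm_params, consts, protocol, i, tol=1e-13)
            assert abs(cf - orc) / abs(orc) < 1e-3

    def test_coupled_mode_close_but_distinct(self, consts, protocol, wm_params):
        # operator splitting error is small but nonzero
        cf = bts_signal(wm_params, consts, protocol, 3)
        cp = simulate_steady_state(
            wm_params, consts, protocol, 3, tol=1e-13, mode="coupled"
        )
        rel = abs(cf - cp) / abs(cp)
        assert 0 < rel < 0.02

    def test_single_period_contract(self, consts, protocol, wm_params):
        s = simulate_steady_state(
            wm_params, consts, protocol, 0, n_reps=1, tol=np.inf
        )
        assert np.isfinite(s)

    def test_nonconvergence_raises(self, consts, protocol, wm_params):
        with pytest.raises(ConvergenceError):
            simulate_steady_state(wm_params, consts, protocol, 0, n_reps=2, tol=1e-14)


class TestJacobian:
    def test_i0_column_is_linear(self, consts, protocol, wm_params, mc):
        J = signal_jacobian(wm_params, consts, protocol)
        mags = np.abs(bts_signal_series(wm_params, consts, protocol))
        assert np.allclose(J[:, 0], mags / wm_params.i0, rtol=1e-10)

    def test_matches_central_differences(self, consts, protocol, wm_params, mc):
        J = signal_jacobian(wm_params, consts, protocol)
        base = wm_params.as_array()
        scales = np.maximum(np.abs(base), 1e-2)
        for j in range(4):
            h = 1e-6 * scales[j]
            hi, lo = base.copy(), base.copy()
            hi[j] += h
            lo[j] -= h
            fd = (
                signal_magnitude_series(tuple(hi), mc)
                - signal_magnitude_series(tuple(lo), mc)
            ) / (2 * h)
            assert np.allclose(J[:, j], fd, rtol=1e-4, atol=1e-9 * np.abs(fd).max())

    def test_boundary_fallback_flagged(self, consts, protocol):
        p = TissueParams(1.0, 1.0, 0.0, 0.0)
        with pytest.warns(RuntimeWarning):
            J = signal_jacobian(p, consts, protocol)
        assert np.all(np.isfinite(J))


def test_in_vivo_protocol_structure():
    prot = in_vivo_protocol()
    assert prot.n_measurements == 8
    assert sorted(set(prot.flip_angles_deg)) == [5, 10, 20, 40]
    assert prot.saturation_on.sum() == 4


def test_phantom_protocol_structure(protocol):
    assert protocol.n_measurements == 10
    assert sorted(set(protocol.flip_angles_deg)) == [5, 10, 20, 40, 60]
    assert protocol.pulse.b1_max == pytest.approx(9.128)
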