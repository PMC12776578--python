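"""Closed-form relaxation models: identities, oracle values, scaling laws."""

import cmath
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glassdyn import (
    CMParams,
    CRRInputs,
    DomainError,
    HNMode,
    KWWFit,
    VFTFit,
    cm_primitive_tau,
    dh_infinity,
    donth_crr_length,
    hn_complex_permittivity,
    hn_loss,
    kww_decay,
    phi_from_recovery,
    tau_alpha_from_hn,
    vft_invert,
    vft_tau,
)

SETTINGS = settings(max_examples=50, derandomize=True, deadline=None)


# ---------------------------------------------------------------------------
# Havriliak-Negami permittivity
# ---------------------------------------------------------------------------

class TestHNPermittivity:
    def test_debye_half_height_at_peak(self):
        # Debye mode with tau = 1/(2 pi): loss peak sits at f = 1 Hz, height de/2
        m = HNMode(delta_eps=1.0, tau_hn=1.0 / (2 * math.pi), a=1.0, b=1.0)
        eps = hn_complex_permittivity(np.array([1.0]), [m])
        assert -eps.imag[0] == pytest.approx(0.5, rel=1e-12)

    def test_zero_strength_reduces_to_eps_inf(self):
        f = np.logspace(-2, 7, 50)
        m = HNMode(delta_eps=1e-300, tau_hn=1e-3, a=0.5, b=0.7)
        eps = hn_complex_permittivity(f, [m], eps_inf=3.2)
        np.testing.assert_allclose(eps.real, 3.2, rtol=1e-10)
        np.testing.assert_allclose(eps.imag, 0.0, atol=1e-290)

    def test_matches_direct_complex_oracle(self):
        # independent per-frequency complex arithmetic with cmath
        de, tau, a, b = 2.0, 1e-3, 0.8, 0.5
        f_spots = np.logspace(-2, 7, 20)
        m = HNMode(delta_eps=de, tau_hn=tau, a=a, b=b)
        eps = hn_complex_permittivity(f_spots, [m], eps_inf=1.0)
        for fk, ek in zip(f_spots, eps):
            w = 2 * math.pi * fk
            oracle = 1.0 + de / (1 + (1j * w * tau) ** a) ** b
            assert cmath.isclose(ek, oracle, rel_tol=1e-12)

    def test_loss_nonnegative_and_conductivity_adds_low_freq_tail(self):
        f = np.logspace(-2, 7, 90)
        m = HNMode(delta_eps=3.0, tau_hn=1e-4, a=0.7, b=0.8)
        loss0 = hn_loss(f, [m])
        loss_sig = hn_loss(f, [m], sigma_dc=1e-12)
        assert np.all(loss0 >= 0)
        assert loss_sig[0] > loss0[0]
        np.testing.assert_allclose(loss_sig[-1], loss0[-1], rtol=1e-3)

    def test_input_validation(self):
        m = HNMode(delta_eps=1.0, tau_hn=1e-3)
        with pytest.raises(DomainError):
            hn_complex_permittivity(np.array([-1.0, 1.0]), [m])
        with pytest.raises(DomainError):
            hn_complex_permittivity(np.array([2.0, 1.0]), [m])
        with pytest.raises(DomainError):
            HNMode(delta_eps=1.0, tau_hn=1e-3, a=1.2)

    def test_cc_loss_peak_at_reciprocal_tau(self):
        # Cole-Cole is symmetric: peak frequency = 1/(2 pi tau) on a dense grid
        tau = 1e-4
        f = np.logspace(0, 7, 5000)
        for a in (0.3, 0.6, 1.0):
            loss = hn_loss(f, [HNMode(delta_eps=1.0, tau_hn=tau, a=a, b=1.0)])
            f_pk = f[np.argmax(loss)]
            assert abs(math.log10(f_pk * 2 * math.pi * tau)) < 2e-3


# ---------------------------------------------------------------------------
# HN -> alpha relaxation time
# ---------------------------------------------------------------------------

class TestTauAlphaFromHN:
    def test_debye_identity(self):
        m = HNMode(delta_eps=1.0, tau_hn=5.0, a=1.0, b=1.0)
        assert tau_alpha_from_hn(m) == pytest.approx(5.0, rel=1e-14)

    def test_asymmetric_oracle_value(self):
        # independent arithmetic: sin(0.4 pi/3)^1.25 / sin(0.8 pi/3)^1.25
        m = HNMode(delta_eps=1.0, tau_hn=1.0, a=0.8, b=0.5)
        assert tau_alpha_from_hn(m) == pytest.approx(0.470760268, rel=1e-8)

    @SETTINGS
    @given(a=st.floats(0.05, 1.0), tau=st.floats(1e-9, 1e3))
    def test_cole_cole_reduces_to_tau_hn(self, a, tau):
        # b = 1 makes both sine factors equal: tau_alpha == tau_HN exactly
        m = HNMode(delta_eps=1.0, tau_hn=tau, a=a, b=1.0)
        assert tau_alpha_from_hn(m) == pytest.approx(tau, rel=1e-12)


# ---------------------------------------------------------------------------
# VFT
# ---------------------------------------------------------------------------

class TestVFT:
    def test_forward_oracle_value(self):
        # scalar plug-in: tau = 1e-14 exp(6.83*279/(341.15-279))
        fit = VFTFit(log10_tau_inf=-14.0, D=6.83, T0=279.0)
        oracle = 1e-14 * math.exp(6.83 * 279.0 / (341.15 - 279.0))
        assert vft_tau(341.15, fit) == pytest.approx(oracle, rel=1e-12)

    def test_small_d_limit_approaches_prefactor(self):
        fit = VFTFit(log10_tau_inf=-14.0, D=1e-8, T0=280.0)
        assert vft_tau(400.0, fit) == pytest.approx(1e-14, rel=1e-6)

    def test_domain_error_below_t0(self):
        fit = VFTFit(log10_tau_inf=-14.0, D=6.33, T0=280.0)
        with pytest.raises(DomainError):
            vft_tau(279.0, fit)

    @SETTINGS
    @given(
        lti=st.floats(-16.0, -10.0),
        D=st.floats(2.0, 20.0),
        T0=st.floats(150.0, 350.0),
        dT=st.floats(5.0, 200.0),
    )
    def test_roundtrip_to_nanokelvin(self, lti, D, T0, dT):
        fit = VFTFit(log10_tau_inf=lti, D=D, T0=T0)
        T = T0 + dT
        assert vft_invert(vft_tau(T, fit), fit) == pytest.approx(T, abs=1e-9)

    def test_strictly_decreasing_in_temperature(self):
        fit = VFTFit(log10_tau_inf=-14.0, D=6.33, T0=280.0)
        T = np.linspace(285.0, 400.0, 200)
        assert np.all(np.diff(vft_tau(T, fit)) < 0)


# ---------------------------------------------------------------------------
# Coupling Model
# ---------------------------------------------------------------------------

class TestCouplingModel:
    def test_beta_one_is_identity(self):
        assert cm_primitive_tau(7.0, beta_kww=1.0) == pytest.approx(7.0, rel=1e-14)

    def test_log_domain_oracle(self):
        # 10^(0.31*log10(2e-12) + 0.69*2)
        val = cm_primitive_tau(100.0, beta_kww=0.69, params=CMParams(n=0.31, tc=2e-12))
        assert val == pytest.approx(5.6666e-3, rel=1e-3)

    def test_crossover_fixed_point(self):
        for n in (0.0, 0.3, 0.7):
            assert cm_primitive_tau(2e-12, params=CMParams(n=n)) == pytest.approx(2e-12, rel=1e-12)

    @SETTINGS
    @given(n=st.floats(0.05, 0.9), tau=st.floats(1e-9, 1e4))
    def test_primitive_time_not_slower_than_alpha(self, n, tau):
        tau = max(tau, 2e-12)
        assert cm_primitive_tau(tau, params=CMParams(n=n)) <= tau * (1 + 1e-12)

    def test_monotone_in_tau_and_n(self):
        taus = np.logspace(-6, 3, 30)
        jg = cm_primitive_tau(taus, beta_kww=0.7)
        assert np.all(np.diff(jg) > 0)
        vals = [cm_primitive_tau(10.0, params=CMParams(n=n)) for n in (0.1, 0.3, 0.5, 0.7)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


# ---------------------------------------------------------------------------
# Donth CRR length
# ---------------------------------------------------------------------------

def _crr(tg=328.4, dtg=2.0, rho=1410.0, cpg=1620.0, cpl=2070.0):
    return donth_crr_length(CRRInputs(tg_onset=tg, half_width=dtg, rho=rho, cpg=cpg, cpl=cpl))


class TestDonth:
    def test_si_plug_in_oracle(self):
        # symbolic plug-in with the measured density and heat capacities
        assert _crr() == pytest.approx(2.0374e-9, rel=1e-3)
        assert 1e-9 < _crr() < 3e-9  # plausibility: organic glasses are ~2 nm

    def test_vanishing_heat_capacity_contrast(self):
        assert _crr(cpg=2070.0 - 1e-6) < 1e-11

    def test_width_scaling_law(self):
        assert _crr(dtg=4.0) / _crr(dtg=2.0) == pytest.approx(2 ** (-2 / 3), rel=1e-12)

    @SETTINGS
    @given(scale=st.floats(1.1, 10.0))
    def test_density_scaling_law(self, scale):
        assert _crr(rho=1410.0 * scale) / _crr() == pytest.approx(scale ** (-1 / 3), rel=1e-9)

    def test_inverted_heat_capacities_rejected(self):
        with pytest.raises(DomainError):
            CRRInputs(tg_onset=328.4, half_width=2.0, rho=1410.0, cpg=2070.0, cpl=1620.0)


# ---------------------------------------------------------------------------
# KWW / enthalpy relations
# ---------------------------------------------------------------------------

class TestKWWRelations:
    def test_phi_at_tau_is_inverse_e(self):
        for beta in (0.3, 0.48, 1.0):
            assert kww_decay(123.4, 123.4, beta) == pytest.approx(math.exp(-1), rel=1e-12)

    def test_dh_infinity_product(self):
        assert dh_infinity(0.45, 55.2, 35.2) == pytest.approx(9.0, rel=1e-12)

    def test_phi_from_recovery_midpoint(self):
        assert phi_from_recovery(4.5, 9.0) == pytest.approx(0.5, rel=1e-12)

    def test_over_recovery_flags_without_clipping(self):
        with pytest.warns(RuntimeWarning):
            phi = phi_from_recovery(np.array([9.5, 1.0]), 9.0)
        assert phi[0] < 0  # returned as-is, not clipped

    def test_monotone_nonincreasing(self):
        t = np.logspace(0, 5, 100)
        phi = kww_decay(t, 500.0, 0.48)
        assert np.all(np.diff(phi) <= 0)
        assert np.all((phi > 0) & (phi <= 1))

    def test_tau_beta_is_recomputed_property(self):
        fit = KWWFit(tau_alpha=1890.0, beta_kww=0.87, tau_unit="min")
        assert fit.tau_beta == pytest.approx(1890.0**0.87, rel=1e-14)
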