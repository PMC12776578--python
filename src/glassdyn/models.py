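"""Closed-form relaxation models.

The pure functions here are the physics core that everything else composes:
the Havriliak–Negami permittivity, the HN→alpha relaxation-time conversion,
the VFT law and its inverse, the Coupling-Model primitive time, the Donth
cooperativity length, and the KWW enthalpy-recovery relations.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

from .errors import DomainError
from .parameters import (
    EPS0,
    K_BOLTZMANN,
    CMParams,
    CRRInputs,
    HNMode,
    VFTFit,
)

__all__ = [
    "hn_complex_permittivity",
    "tau_alpha_from_hn",
    "vft_tau",
    "vft_invert",
    "cm_primitive_tau",
    "donth_crr_length",
    "kww_decay",
    "dh_infinity",
    "phi_from_recovery",
    "arrhenius_tau",
]


def hn_complex_permittivity(
    freq_hz: np.ndarray,
    modes: Sequence[HNMode],
    eps_inf: float = 0.0,
    sigma_dc: float = 0.0,
    s_exp: float = 1.0,
) -> np.ndarray:
    """Complex permittivity of a sum of HN modes plus a dc-conductivity term.

    ``eps*(w) = eps_inf + sum_k de_k / (1 + (i w tau_k)^a_k)^b_k - i sigma/(eps0 w^s)``

    with ``w = 2 pi f``.  The returned array uses the physics sign convention
    ``eps* = eps' - i eps''`` so the loss is ``-imag``.

    Parameters
    ----------
    freq_hz : array
        Strictly positive frequencies, ascending, Hz.
    modes : sequence of HNMode
    eps_inf : float
        High-frequency limit permittivity.
    sigma_dc : float
        dc conductivity, S/m (>= 0).
    s_exp : float
        Conductivity exponent in (0, 1]; 1 is pure ohmic conduction.
    """
    f = np.asarray(freq_hz, dtype=float)
    if f.ndim != 1 or f.size == 0:
        raise DomainError("freq_hz must be a non-empty 1-D array")
    if np.any(f <= 0):
        raise DomainError("frequencies must be strictly positive")
    if np.any(np.diff(f) <= 0):
        raise DomainError("frequencies must be strictly ascending")
    if sigma_dc < 0:
        raise DomainError("sigma_dc must be >= 0")
    if not 0 < s_exp <= 1:
        raise DomainError("conductivity exponent must be in (0, 1]")

    w = 2.0 * np.pi * f
    eps = np.full_like(f, eps_inf, dtype=complex)
    for m in modes:
        eps = eps + m.delta_eps / (1.0 + (1j * w * m.tau_hn) ** m.a) ** m.b
    if sigma_dc > 0:
        eps = eps - 1j * sigma_dc / (EPS0 * w**s_exp)
    return eps


def hn_loss(freq_hz, modes, eps_inf=0.0, sigma_dc=0.0, s_exp=1.0):
    """Dielectric loss eps''(f) of the HN model (nonnegative for valid modes)."""
    return -hn_complex_permittivity(freq_hz, modes, eps_inf, sigma_dc, s_exp).imag


def tau_alpha_from_hn(mode: HNMode) -> float:
    """Alpha relaxation time from HN parameters.

    ``tau_a = tau_HN * [sin(pi a b/(2+2b))]^(1/a) * [sin(pi a/(2+2b))]^(-1/a)``

    reduces to ``tau_HN`` in the Debye (a=b=1) and Cole–Cole (b=1) cases.
    """
    a, b = mode.a, mode.b
    s1 = math.sin(math.pi * a * b / (2.0 + 2.0 * b))
    s2 = math.sin(math.pi * a / (2.0 + 2.0 * b))
    return mode.tau_hn * (s1 / s2) ** (1.0 / a)


def vft_tau(T, fit: VFTFit):
    """VFT relaxation time ``tau = tau_inf * exp(D T0 / (T - T0))`` (seconds).

    Raises :class:`DomainError` for any temperature at or below T0.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= fit.T0):
        raise DomainError(f"VFT law requires T > T0 = {fit.T0} K")
    out = fit.tau_inf * np.exp(fit.D * fit.T0 / (T - fit.T0))
    return float(out) if out.ndim == 0 else out


def vft_invert(tau, fit: VFTFit):
    """Temperature at which the VFT law reaches ``tau``: ``T = T0 (1 + D/ln(tau/tau_inf))``."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= fit.tau_inf):
        raise DomainError("vft_invert requires tau > tau_inf")
    out = fit.T0 * (1.0 + fit.D / np.log(tau / fit.tau_inf))
    return float(out) if out.ndim == 0 else out


def vft_tg(fit: VFTFit) -> float:
    """Glass-transition temperature defined by ``tau(T_g) = tg_tau`` (K)."""
    return float(vft_invert(fit.tg_tau, fit))


def cm_primitive_tau(tau_alpha, beta_kww: float | None = None, params: CMParams | None = None):
    """Coupling-Model primitive (Johari–Goldstein) time.

    ``tau_JG ~ tau_0 = tc^n * tau_alpha^(1-n)`` with ``n = 1 - beta_kww``.
    Evaluated in log space for numerical range. ``tau_JG <= tau_alpha``
    whenever ``tau_alpha >= tc``, with equality at n = 0.
    """
    if params is None:
        if beta_kww is None:
            raise DomainError("provide beta_kww or params")
        params = CMParams.from_beta(beta_kww)
    tau = np.asarray(tau_alpha, dtype=float)
    if np.any(tau <= 0):
        raise DomainError("tau_alpha must be > 0")
    log_tau = params.n * np.log(params.tc) + (1.0 - params.n) * np.log(tau)
    out = np.exp(log_tau)
    return float(out) if out.ndim == 0 else out


def donth_crr_length(inputs: CRRInputs) -> float:
    """Donth cooperativity (CRR) length in meters.

    ``L = { 3 k Tg^2 / (4 pi rho dTg^2) * (1/Cpg - 1/Cpl) }^(1/3)``

    with the onset T_g, half the transition width dTg, SI density and heat
    capacities.  Typical organic glasses give a few nanometres.
    """
    arg = (
        3.0
        * K_BOLTZMANN
        * inputs.tg_onset**2
        / (4.0 * math.pi * inputs.rho * inputs.half_width**2)
        * (1.0 / inputs.cpg - 1.0 / inputs.cpl)
    )
    # cpl > cpg is enforced by CRRInputs, so arg > 0 here
    return arg ** (1.0 / 3.0)


def kww_decay(t, tau: float, beta: float):
    """Stretched-exponential relaxation function ``Phi = exp(-(t/tau)^beta)``."""
    if not tau > 0:
        raise DomainError("tau must be > 0")
    if not 0 < beta <= 1:
        raise DomainError("beta must be in (0, 1]")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("t must be >= 0")
    out = np.exp(-((t / tau) ** beta))
    return float(out) if out.ndim == 0 else out


def dh_infinity(delta_cp: float, tg: float, ta: float) -> float:
    """Equilibrium recovery enthalpy ``dH_inf = dCp * (Tg - Ta)`` in J/g.

    ``tg`` and ``ta`` may both be in K or both in degC (only the difference
    enters); ``delta_cp`` in J/(g·K).
    """
    if not tg > ta:
        raise DomainError("requires Tg > Ta (annealing below the glass transition)")
    if not delta_cp > 0:
        raise DomainError("delta_cp must be > 0")
    return delta_cp * (tg - ta)


def phi_from_recovery(dh_t, dh_inf: float):
    """Relaxation function from recovered enthalpy: ``Phi = 1 - dH_t/dH_inf``.

    Values outside [0, 1] are returned as-is (never clipped); callers decide
    how to treat over-recovery.  A RuntimeWarning is emitted when any
    ``dh_t`` exceeds ``dh_inf``.
    """
    if not dh_inf > 0:
        raise DomainError("dh_inf must be > 0")
    dh = np.asarray(dh_t, dtype=float)
    if np.any(dh > dh_inf):
        import warnings

        warnings.warn(
            "recovered enthalpy exceeds dh_inf (over-recovery); Phi < 0",
            RuntimeWarning,
            stacklevel=2,
        )
    out = 1.0 - dh / dh_inf
    return float(out) if out.ndim == 0 else out


def arrhenius_tau(T, tau0: float, ea_kj_mol: float):
    """Arrhenius relaxation time ``tau = tau0 * exp(Ea/(R T))`` (same unit as tau0)."""
    from .parameters import R_GAS

    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise DomainError("T must be > 0 K")
    out = tau0 * np.exp(ea_kj_mol * 1000.0 / (R_GAS * T))
    return float(out) if out.ndim == 0 else out
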