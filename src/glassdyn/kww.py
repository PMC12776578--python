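"""Numeric loss spectrum of the KWW (stretched-exponential) decay.

The dielectric loss of a relaxation with correlation function
``Phi(t) = exp(-(t/tau)^beta)`` is the one-sided Fourier sine transform of
the retardation spectrum ``-dPhi/dt``:

    chi''(w) = int_0^inf (-dPhi/dt) sin(w t) dt

There is no closed form for beta < 1, so the transform is evaluated
numerically on a logarithmic time grid with a piecewise-linear Filon rule:
on each panel the smooth factor ``-dPhi/dt`` is interpolated linearly and
``int (c0 + c1 t) sin(w t) dt`` integrated exactly, which stays accurate at
frequencies far above the relaxation rate where a plain trapezoid rule would
under-resolve the oscillation.  Shapes are cached per beta on a 0.01 grid.
The exact Debye limit (beta = 1, ``chi'' = wt/(1+(wt)^2)``) validates the
quadrature.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .errors import DomainError

#: log10(w*tau) grid on which cached shapes are evaluated
_LOGWT = np.arange(-4.0, 4.0 + 1e-9, 0.02)

# time grid (tau = 1 units): 12 decades, 2048 points
_T_GRID = np.logspace(-8.0, 4.0, 2048)


def _kww_rate(t: np.ndarray, beta: float) -> np.ndarray:
    """-dPhi/dt = beta * t^(beta-1) * exp(-t^beta) for tau = 1."""
    return beta * t ** (beta - 1.0) * np.exp(-(t**beta))


def _filon_sine(w: np.ndarray, t: np.ndarray, g: np.ndarray) -> np.ndarray:
    """``int g(t) sin(w t) dt`` with g piecewise linear on the grid t.

    Vectorized over frequencies ``w`` (1-D); returns shape (len(w),).
    """
    t1, t2 = t[:-1], t[1:]
    g1, g2 = g[:-1], g[1:]
    slope = (g2 - g1) / (t2 - t1)  # c1 per panel
    c0 = g1 - slope * t1  # c0 per panel

    W = w[:, None]
    x1, x2 = W * t1[None, :], W * t2[None, :]
    s1, s2 = np.sin(x1), np.sin(x2)
    cth1, cth2 = np.cos(x1), np.cos(x2)
    # int sin(wt) dt over panel
    I0 = (cth1 - cth2) / W
    # int t sin(wt) dt over panel
    I1 = (s2 - x2 * cth2 - s1 + x1 * cth1) / W**2
    return np.sum(c0[None, :] * I0 + slope[None, :] * I1, axis=1)


def kww_loss_spectrum(omega_tau: np.ndarray, beta: float) -> np.ndarray:
    """Normalized-strength KWW loss chi''(w) at reduced frequency ``w*tau``."""
    if not 0 < beta <= 1:
        raise DomainError("beta must be in (0, 1]")
    wt = np.asarray(omega_tau, dtype=float)
    if np.any(wt <= 0):
        raise DomainError("omega_tau must be > 0")
    if beta == 1.0:
        return wt / (1.0 + wt**2)
    g = _kww_rate(_T_GRID, beta)
    return _filon_sine(wt.ravel(), _T_GRID, g).reshape(wt.shape)


@lru_cache(maxsize=256)
def _cached_shape(beta_centi: int):
    """Peak-normalized loss shape for beta = beta_centi/100.

    Returns ``(x, y, log10_wt_max)`` with ``x = log10(w/w_max)`` and
    ``y = chi''/chi''_max`` on a dense grid around the peak.
    """
    beta = beta_centi / 100.0
    y = kww_loss_spectrum(10.0**_LOGWT, beta)
    imax = int(np.argmax(y))
    if imax in (0, len(y) - 1):  # pragma: no cover - grid spans the peak for all beta
        raise DomainError("KWW loss peak outside internal grid")
    # parabolic sub-grid refinement of the peak position/height in log f
    ym1, y0, yp1 = y[imax - 1], y[imax], y[imax + 1]
    denom = ym1 - 2 * y0 + yp1
    shift = 0.5 * (ym1 - yp1) / denom if denom != 0 else 0.0
    log_wt_max = _LOGWT[imax] + shift * (_LOGWT[1] - _LOGWT[0])
    y_max = y0 - 0.25 * (ym1 - yp1) * shift
    return _LOGWT - log_wt_max, y / y_max, log_wt_max


def kww_normalized_shape(beta: float):
    """Peak-normalized KWW loss curve.

    Returns ``(x, y)`` where ``x = log10(f/f_max)`` and ``y = loss/loss_max``;
    beta is snapped to the 0.01 cache grid.
    """
    beta_centi = int(round(beta * 100))
    if not 20 <= beta_centi <= 100:
        raise DomainError("beta must be in [0.20, 1.00] for shape analysis")
    x, y, _ = _cached_shape(beta_centi)
    return x, y


def kww_peak_omega_tau(beta: float) -> float:
    """Reduced peak frequency ``w_max * tau`` of the KWW loss."""
    beta_centi = int(round(beta * 100))
    _, _, log_wt_max = _cached_shape(beta_centi)
    return 10.0**log_wt_max
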