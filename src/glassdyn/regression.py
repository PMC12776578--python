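"""Temperature-law regressors (scikit-learn style).

:class:`ArrheniusRegressor` is an OLS fit of ``ln q`` on reciprocal
temperature; :class:`VFTRegressor` is a bounded nonlinear least-squares fit
of ``log10 tau`` on temperature, optionally with the pre-exponential fixed
and/or an exact T_g constraint (``tau(T_g) = 100 s`` by convention).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import DomainError, FitError
from .parameters import R_GAS, ArrheniusFit, VFTFit

_LN10 = np.log(10.0)


def _column(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2 and X.shape[1] == 1:
        X = X[:, 0]
    if X.ndim != 1:
        raise DomainError("X must be 1-D or a single-column 2-D array")
    return X


class ArrheniusRegressor(BaseEstimator, RegressorMixin):
    """OLS Arrhenius fit ``ln q = ln A + (Ea/R) * (1/T)``.

    ``fit(X, y)`` takes X = reciprocal temperature (1/K) and y = ln of the
    fitted quantity (any unit; unit scaling shifts only the intercept).

    Attributes
    ----------
    ea_ : activation energy, kJ/mol
    se_ea_ : standard error of ``ea_`` (0 for a two-point fit)
    ln_prefactor_ : fitted intercept
    result_ : the :class:`~glassdyn.parameters.ArrheniusFit` container
    """

    def fit(self, X, y):
        x = _column(X)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise DomainError("X and y must have the same length")
        if x.size < 2:
            raise FitError("Arrhenius fit needs at least 2 points")
        if np.ptp(x) == 0:
            raise FitError("all temperatures identical: singular Arrhenius fit")
        n = x.size
        A = np.column_stack([np.ones(n), x])
        coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
        intercept, slope = coef
        resid = y - A @ coef
        if n > 2:
            s2 = float(resid @ resid) / (n - 2)
            sxx = float(np.sum((x - x.mean()) ** 2))
            se_slope = np.sqrt(s2 / sxx)
        else:
            se_slope = 0.0
        self.ea_ = slope * R_GAS / 1000.0
        self.se_ea_ = se_slope * R_GAS / 1000.0
        self.ln_prefactor_ = float(intercept)
        self.result_ = ArrheniusFit(
            ea=float(self.ea_), ln_prefactor=self.ln_prefactor_,
            se_ea=float(self.se_ea_), n_points=int(n),
        )
        return self

    def predict(self, X):
        x = _column(X)
        return self.ln_prefactor_ + self.ea_ * 1000.0 / R_GAS * x


def arrhenius_fit(inv_T, ln_q) -> ArrheniusFit:
    """OLS of ``ln_q`` on reciprocal temperature; returns an :class:`ArrheniusFit`."""
    return ArrheniusRegressor().fit(np.asarray(inv_T), np.asarray(ln_q)).result_


class VFTRegressor(BaseEstimator, RegressorMixin):
    """Nonlinear least squares of ``log10 tau`` against temperature (VFT law).

    ``fit(X, y)`` takes X = temperature (K) and y = log10 of tau (s).

    Parameters
    ----------
    fix_log_tau_inf : float or None
        If given, the pre-exponential is held fixed (the conventional choice
        is -14 for a phonon-like attempt time).
    tg_constraint : (T_g, tau_g) or None
        If given, the fitted curve is forced through ``tau(T_g) = tau_g``
        exactly by eliminating one parameter.
    tg_tau : float
        Relaxation time defining T_g for the fitted law (default 100 s).

    Attributes
    ----------
    result_ : :class:`~glassdyn.parameters.VFTFit`
    tg_ : temperature where the fitted law reaches ``tg_tau`` (K)
    """

    def __init__(self, fix_log_tau_inf=None, tg_constraint=None, tg_tau=100.0):
        self.fix_log_tau_inf = fix_log_tau_inf
        self.tg_constraint = tg_constraint
        self.tg_tau = tg_tau

    # --- model in log10 space -------------------------------------------
    @staticmethod
    def _log10_tau(T, log10_tau_inf, D, T0):
        return log10_tau_inf + D * T0 / (T - T0) / _LN10

    def fit(self, X, y):
        T = _column(X)
        y = np.asarray(y, dtype=float)
        if T.shape != y.shape:
            raise DomainError("X and y must have the same length")
        n_free = 3 - (self.fix_log_tau_inf is not None) - (self.tg_constraint is not None)
        if T.size < max(n_free, 3):
            raise FitError(f"VFT fit needs at least {max(n_free, 3)} points, got {T.size}")

        Tmin = float(T.min())
        T0_init = max(Tmin - 50.0, 1.0)
        D_init = 6.0
        lti_init = -14.0

        fix_lti = self.fix_log_tau_inf
        cons = self.tg_constraint

        def unpack(p):
            """Return (log10_tau_inf, D, T0) from the free-parameter vector."""
            if cons is not None and fix_lti is not None:
                (T0,) = p
                Tg, tau_g = cons
                D = np.log(tau_g / 10.0**fix_lti) * (Tg - T0) / T0
                return fix_lti, D, T0
            if cons is not None:
                D, T0 = p
                Tg, tau_g = cons
                lti = np.log10(tau_g) - D * T0 / (Tg - T0) / _LN10
                return lti, D, T0
            if fix_lti is not None:
                D, T0 = p
                return fix_lti, D, T0
            lti, D, T0 = p
            return lti, D, T0

        def resid(p):
            lti, D, T0 = unpack(p)
            return self._log10_tau(T, lti, D, T0) - y

        eps = 1e-3
        if cons is not None and fix_lti is not None:
            p0, lo, hi = [T0_init], [1.0], [Tmin - eps]
        elif cons is not None or fix_lti is not None:
            p0, lo, hi = [D_init, T0_init], [1e-3, 1.0], [1e3, Tmin - eps]
        else:
            p0, lo, hi = [lti_init, D_init, T0_init], [-30.0, 1e-3, 1.0], [0.0, 1e3, Tmin - eps]
        if cons is not None:
            # T0 must also stay below the constrained Tg
            hi[-1] = min(hi[-1], cons[0] - eps)
            p0[-1] = min(p0[-1], hi[-1] - 1.0)

        sol = least_squares(resid, p0, bounds=(lo, hi), method="trf", xtol=1e-14, ftol=1e-14)
        lti, D, T0 = unpack(sol.x)
        self.result_ = VFTFit(
            log10_tau_inf=float(lti), D=float(D), T0=float(T0), tg_tau=float(self.tg_tau)
        )
        from .models import vft_tg

        self.tg_ = vft_tg(self.result_)
        self.residual_rms_ = float(np.sqrt(np.mean(sol.fun**2)))
        self.converged_ = bool(sol.status > 0)
        return self

    def predict(self, X):
        T = _column(X)
        r = self.result_
        return self._log10_tau(T, r.log10_tau_inf, r.D, r.T0)
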