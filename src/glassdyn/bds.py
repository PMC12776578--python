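"""Broadband-dielectric-spectroscopy pipeline.

Deconvolutes loss spectra into Havriliak–Negami / Cole–Cole modes, tracks
the modes across temperature into a relaxation map, fits Arrhenius and VFT
temperature laws, extracts the KWW stretching exponent from the alpha-peak
shape, predicts Johari–Goldstein times with the Coupling Model, and
extrapolates alpha times below T_g by time–temperature-superposition
(master-plot) shifting.

Fitting happens on ``log10(eps'')`` versus ``log10(f)``: the loss spans many
decades over the 1e-2–1e7 Hz window and linear-space residuals would drown
the weak secondary modes under the alpha peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares, minimize_scalar
from sklearn.base import BaseEstimator

from .errors import DataError, DomainError, FitError, TruncatedPeakError
from .kww import kww_normalized_shape
from .models import hn_loss, tau_alpha_from_hn
from .parameters import EPS0, HNMode, VFTFit
from .regression import ArrheniusRegressor, VFTRegressor

__all__ = [
    "DielectricSpectrum",
    "SpectrumFit",
    "RelaxationMap",
    "HNSpectrumFitter",
    "KWWShapeFitter",
    "fit_spectrum",
    "track_modes",
    "kww_shape_fit",
    "fit_alpha_vft",
    "predict_jg",
    "masterplot_extrapolate",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class DielectricSpectrum:
    """One temperature's dielectric spectrum: (f, eps', eps'')."""

    temperature: float  # K
    freq: np.ndarray  # Hz, strictly ascending
    eps_real: np.ndarray
    eps_imag: np.ndarray  # loss, >= 0 after cleaning
    sample: str = ""
    thickness_mm: float | None = None

    def __post_init__(self):
        self.freq = np.asarray(self.freq, dtype=float)
        self.eps_real = np.asarray(self.eps_real, dtype=float)
        self.eps_imag = np.asarray(self.eps_imag, dtype=float)
        n = self.freq.size
        if n < 8:
            raise DataError(f"spectrum needs >= 8 points, got {n}")
        if self.eps_real.size != n or self.eps_imag.size != n:
            raise DataError("freq, eps_real, eps_imag must have equal length")
        if np.any(np.diff(self.freq) <= 0):
            bad = int(np.flatnonzero(np.diff(self.freq) <= 0)[0]) + 1
            raise DataError(f"frequency not strictly increasing at row {bad}")

    def cleaned(self) -> "DielectricSpectrum":
        """Copy with non-positive loss points dropped (log-space fitting)."""
        keep = self.eps_imag > 0
        if keep.sum() < 8:
            raise DataError("fewer than 8 positive-loss points after cleaning")
        return DielectricSpectrum(
            temperature=self.temperature,
            freq=self.freq[keep],
            eps_real=self.eps_real[keep],
            eps_imag=self.eps_imag[keep],
            sample=self.sample,
            thickness_mm=self.thickness_mm,
        )


@dataclass
class SpectrumFit:
    """Fitted mode set for one spectrum."""

    modes: list[HNMode]
    eps_inf: float
    sigma_dc: float
    residual_rms: float  # rms of log10-loss residuals
    converged: bool
    temperature: float  # K

    def __post_init__(self):
        labels = [m.label for m in self.modes]
        if labels.count("alpha") > 1:
            raise DomainError("at most one mode may be labeled alpha")
        if len(labels) != len(set(labels)):
            raise DomainError("mode labels must be unique within a spectrum fit")
        for m in self.modes:
            if m.label != "alpha" and m.b != 1.0:
                raise DomainError("secondary (non-alpha) modes must be Cole–Cole (b = 1)")

    def mode(self, label: str) -> HNMode | None:
        for m in self.modes:
            if m.label == label:
                return m
        return None

    def loss(self, freq_hz) -> np.ndarray:
        return hn_loss(freq_hz, self.modes, eps_inf=self.eps_inf, sigma_dc=self.sigma_dc)


@dataclass
class RelaxationMap:
    """Per-process relaxation times across temperature plus temperature-law fits.

    ``processes`` maps a label to an array of rows ``(T_K, tau_alpha_s,
    delta_eps)``; ``arrhenius`` holds the Arrhenius fit per secondary
    process, ``vft`` the VFT fit for the alpha process and ``jg_predicted``
    the Coupling-Model primitive times.
    """

    processes: dict[str, np.ndarray] = field(default_factory=dict)
    arrhenius: dict = field(default_factory=dict)
    vft: Optional[VFTFit] = None
    jg_predicted: list[tuple[float, float]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def tau(self, label: str) -> np.ndarray:
        return self.processes[label][:, 1]

    def temperatures(self, label: str) -> np.ndarray:
        return self.processes[label][:, 0]


# ---------------------------------------------------------------------------
# spectrum deconvolution
# ---------------------------------------------------------------------------

class HNSpectrumFitter(BaseEstimator):
    """Nonlinear least-squares deconvolution of a loss spectrum into HN modes.

    ``fit(X, y)`` takes X = frequency (Hz) and y = dielectric loss; the
    residual is ``log10(model) - log10(data)``.  The mode template (labels,
    initial guesses) comes from ``template``, either a list of
    :class:`HNMode` or a previous temperature's :class:`SpectrumFit`
    (continuation strategy).  Bounds: 0 < a <= 1; b is fixed at 1 for
    non-alpha modes; strengths and times are fitted in log10 space.

    Parameters
    ----------
    template : list[HNMode] | SpectrumFit
    fit_sigma : bool
        Fit a dc-conductivity term (exponent fixed at ``s_exp``).
    s_exp : float
        Conductivity exponent, default 1 (pure ohmic).
    eps_inf : float
        High-frequency permittivity (affects only eps'; kept fixed).

    Attributes
    ----------
    modes_ : fitted HN modes
    sigma_dc_, residual_rms_, converged_ : fit diagnostics
    result_ : the assembled :class:`SpectrumFit` (temperature filled by
        :func:`fit_spectrum`)
    """

    def __init__(self, template=None, fit_sigma=False, s_exp=1.0, eps_inf=0.0):
        self.template = template
        self.fit_sigma = fit_sigma
        self.s_exp = s_exp
        self.eps_inf = eps_inf

    def _template_modes(self) -> list[HNMode]:
        if self.template is None:
            raise FitError("a mode template (labels + initial guesses) is required")
        if isinstance(self.template, SpectrumFit):
            return list(self.template.modes)
        return list(self.template)

    def fit(self, X, y):
        f = np.asarray(X, dtype=float).ravel()
        loss = np.asarray(y, dtype=float).ravel()
        keep = loss > 0
        f, loss = f[keep], loss[keep]
        modes0 = self._template_modes()

        n_free = sum(3 if m.label != "alpha" else 4 for m in modes0) + bool(self.fit_sigma)
        if f.size < n_free:
            raise FitError(f"{f.size} points cannot constrain {n_free} free parameters")

        # pack: per mode [log10 de, log10 tau, a, (b for alpha)] (+ log10 sigma)
        p0, lo, hi = [], [], []
        for m in modes0:
            p0 += [np.log10(m.delta_eps), np.log10(m.tau_hn), m.a]
            lo += [-6.0, -16.0, 0.02]
            hi += [4.0, 6.0, 1.0]
            if m.label == "alpha":
                p0.append(m.b)
                lo.append(0.02)
                hi.append(1.0)
        if self.fit_sigma:
            p0.append(-12.0)
            lo.append(-20.0)
            hi.append(2.0)
        p0 = np.clip(p0, lo, hi)

        def unpack(p):
            modes, i = [], 0
            for m in modes0:
                lde, ltau, a = p[i : i + 3]
                i += 3
                if m.label == "alpha":
                    b = p[i]
                    i += 1
                else:
                    b = 1.0
                modes.append(
                    HNMode(delta_eps=10.0**lde, tau_hn=10.0**ltau, a=a, b=b, label=m.label)
                )
            sigma = 10.0 ** p[i] if self.fit_sigma else 0.0
            return modes, sigma

        log_data = np.log10(loss)

        def resid(p):
            modes, sigma = unpack(p)
            model = hn_loss(f, modes, sigma_dc=sigma, s_exp=self.s_exp)
            return np.log10(np.maximum(model, 1e-300)) - log_data

        try:
            sol = least_squares(resid, p0, bounds=(lo, hi), method="trf",
                                xtol=1e-15, ftol=1e-15, gtol=1e-15)
            ok = sol.status > 0
        except Exception:  # optimizer failure: best-effort parameters, never raise
            class _Sol:  # noqa: N801 - local stub
                x = np.asarray(p0)
                fun = resid(np.asarray(p0))
            sol, ok = _Sol(), False

        self.modes_, self.sigma_dc_ = unpack(sol.x)
        self.residual_rms_ = float(np.sqrt(np.mean(np.asarray(sol.fun) ** 2)))
        self.converged_ = bool(ok)
        self.result_ = SpectrumFit(
            modes=self.modes_,
            eps_inf=float(self.eps_inf),
            sigma_dc=float(self.sigma_dc_),
            residual_rms=self.residual_rms_,
            converged=self.converged_,
            temperature=float("nan"),
        )
        return self

    def predict(self, X):
        return hn_loss(np.asarray(X, dtype=float).ravel(), self.modes_,
                       sigma_dc=self.sigma_dc_, s_exp=self.s_exp)


def fit_spectrum(spec: DielectricSpectrum, template, fit_sigma=False, eps_inf=None) -> SpectrumFit:
    """Deconvolute one cleaned spectrum using a mode template.

    ``template`` is a list of :class:`HNMode` initial guesses or the previous
    temperature's :class:`SpectrumFit` (continuation).  ``eps_inf`` defaults
    to the high-frequency limit of eps' when available.
    """
    spec = spec.cleaned()
    if eps_inf is None:
        eps_inf = float(np.median(spec.eps_real[-3:])) if spec.eps_real.size else 0.0
    est = HNSpectrumFitter(template=template, fit_sigma=fit_sigma, eps_inf=eps_inf)
    est.fit(spec.freq, spec.eps_imag)
    fit = est.result_
    fit.temperature = float(spec.temperature)
    return fit


# ---------------------------------------------------------------------------
# relaxation map
# ---------------------------------------------------------------------------

def track_modes(fits: Sequence[SpectrumFit], min_coverage: float = 0.5) -> RelaxationMap:
    """Associate fitted modes across temperature into a relaxation map.

    Association follows the mode *labels* (continuity of labelling across
    temperatures), never tau proximity, so processes whose times cross are
    kept separate.  Adjacent-temperature assignments where a different label
    lies within 0.3 decades of tau are flagged as ambiguous.  A label present
    at fewer than ``min_coverage`` of the temperatures is excluded with a
    warning.  Alpha times come from the HN-shape conversion
    (:func:`~glassdyn.models.tau_alpha_from_hn`); Arrhenius fits are attached
    for each secondary process with >= 2 temperatures, a VFT fit for alpha
    with >= 3.
    """
    fits = sorted(fits, key=lambda s: s.temperature)
    if not fits:
        raise FitError("no spectrum fits supplied")
    n_T = len(fits)
    rmap = RelaxationMap()
    labels = sorted({m.label for s in fits for m in s.modes})

    for lab in labels:
        rows = []
        for s in fits:
            m = s.mode(lab)
            if m is None:
                continue
            tau = tau_alpha_from_hn(m)
            rows.append((s.temperature, tau, m.delta_eps))
            # ambiguity check: another label within 0.3 decades at this T
            for other in s.modes:
                if other.label != lab:
                    d = abs(np.log10(tau_alpha_from_hn(other)) - np.log10(tau))
                    if d < 0.3:
                        rmap.warnings.append(
                            f"ambiguous assignment at T={s.temperature:.1f} K: "
                            f"{lab} and {other.label} within {d:.2f} decades"
                        )
        if len(rows) < max(1, int(np.ceil(min_coverage * n_T))) and n_T > 1:
            rmap.warnings.append(
                f"process {lab!r} present at {len(rows)}/{n_T} temperatures; excluded"
            )
            warnings.warn(rmap.warnings[-1], stacklevel=2)
            continue
        arr = np.asarray(rows, dtype=float)
        if len(np.unique(arr[:, 0])) != len(arr):
            raise DataError(f"duplicate temperatures for process {lab!r}")
        rmap.processes[lab] = arr

    for lab, arr in rmap.processes.items():
        if lab == "alpha":
            if len(arr) >= 3:
                rmap.vft = fit_alpha_vft(rmap)
        elif len(arr) >= 2:
            reg = ArrheniusRegressor().fit(1.0 / arr[:, 0], np.log(arr[:, 1]))
            rmap.arrhenius[lab] = reg.result_
    return rmap


def fit_alpha_vft(rmap: RelaxationMap, fix_log_tau_inf=None, tg_constraint=None) -> VFTFit:
    """VFT fit of the alpha process of a relaxation map (log10 tau vs T)."""
    if "alpha" not in rmap.processes:
        raise FitError("relaxation map has no alpha process")
    arr = rmap.processes["alpha"]
    if len(arr) < 3:
        raise FitError("VFT fit needs >= 3 alpha points")
    reg = VFTRegressor(fix_log_tau_inf=fix_log_tau_inf, tg_constraint=tg_constraint)
    reg.fit(arr[:, 0], np.log10(arr[:, 1]))
    rmap.vft = reg.result_
    return reg.result_


def predict_jg(rmap: RelaxationMap, beta_kww: float, tc: float = 2e-12) -> list[tuple[float, float]]:
    """Coupling-Model JG (primitive) times at each alpha-map temperature.

    Applies ``tau_JG = tc^n tau_alpha^(1-n)`` with ``n = 1 - beta_kww`` per
    temperature; the result is attached to the map as ``jg_predicted``.
    """
    from .models import cm_primitive_tau
    from .parameters import CMParams

    params = CMParams.from_beta(beta_kww, tc=tc)
    out = []
    if "alpha" in rmap.processes:
        for T, tau, _ in rmap.processes["alpha"]:
            out.append((float(T), float(cm_primitive_tau(tau, params=params))))
    rmap.jg_predicted = out
    return out


# ---------------------------------------------------------------------------
# alpha-peak shape analysis (KWW)
# ---------------------------------------------------------------------------

class KWWShapeFitter(BaseEstimator):
    """Fit the KWW stretching exponent to a normalized alpha loss peak.

    ``fit(X, y)`` takes X = frequency (Hz) and y = loss within the alpha
    window.  The measured peak, normalized as ``eps''/eps''_max`` versus
    ``f/f_max``, is matched by least squares to the numerically transformed
    KWW loss (one-sided Fourier sine transform of -dPhi/dt).  A free
    amplitude and a free horizontal shift absorb the discretization of the
    measured peak maximum; beta is located by a coarse-to-fine search on the
    0.01 cache grid with parabolic refinement.

    Attributes
    ----------
    beta_ : fitted stretching exponent
    shift_ : residual log10-frequency shift of the model peak
    sse_ : sum of squared residuals at the optimum
    """

    def __init__(self, beta_min=0.20, beta_max=1.00):
        self.beta_min = beta_min
        self.beta_max = beta_max

    @staticmethod
    def _sse_for_beta(beta_centi, x_data, y_data):
        xg, yg = kww_normalized_shape(beta_centi / 100.0)

        def sse_of_shift(c):
            ym = np.interp(x_data - c, xg, yg)
            amp = float(ym @ y_data) / float(ym @ ym)
            r = amp * ym - y_data
            return float(r @ r)

        res = minimize_scalar(sse_of_shift, bounds=(-0.5, 0.5), method="bounded",
                              options={"xatol": 1e-4})
        return res.fun, res.x

    def fit(self, X, y):
        f = np.asarray(X, dtype=float).ravel()
        loss = np.asarray(y, dtype=float).ravel()
        if f.size != loss.size or f.size < 8:
            raise FitError("need >= 8 (f, loss) points in the alpha window")
        imax = int(np.argmax(loss))
        if imax in (0, f.size - 1):
            raise TruncatedPeakError("alpha peak maximum lies at the window edge")
        x = np.log10(f / f[imax])
        yn = loss / loss[imax]

        lo = int(round(self.beta_min * 100))
        hi = int(round(self.beta_max * 100))
        coarse = list(range(lo, hi + 1, 5))
        if coarse[-1] != hi:
            coarse.append(hi)
        scores = {bc: self._sse_for_beta(bc, x, yn) for bc in coarse}
        best = min(scores, key=lambda b: scores[b][0])
        for bc in range(max(lo, best - 5), min(hi, best + 5) + 1):
            if bc not in scores:
                scores[bc] = self._sse_for_beta(bc, x, yn)
        best = min(scores, key=lambda b: scores[b][0])

        beta = best / 100.0
        if lo < best < hi and (best - 1) in scores and (best + 1) in scores:
            ym1, y0, yp1 = scores[best - 1][0], scores[best][0], scores[best + 1][0]
            denom = ym1 - 2 * y0 + yp1
            if denom > 0:
                beta += 0.01 * 0.5 * (ym1 - yp1) / denom
        self.beta_ = float(np.clip(beta, self.beta_min, self.beta_max))
        self.sse_, self.shift_ = scores[best]
        return self

    def predict(self, X):
        """Normalized model loss at frequencies X (Hz) relative to the data peak."""
        raise NotImplementedError("use kww_normalized_shape(beta_) for the model curve")


def kww_shape_fit(spec: DielectricSpectrum, alpha_window: tuple[float, float]) -> float:
    """KWW stretching exponent of the alpha peak inside ``alpha_window`` (Hz)."""
    fmin, fmax = alpha_window
    mask = (spec.freq >= fmin) & (spec.freq <= fmax)
    if mask.sum() < 8:
        raise FitError("alpha window contains fewer than 8 points")
    est = KWWShapeFitter().fit(spec.freq[mask], spec.eps_imag[mask])
    return est.beta_


# ---------------------------------------------------------------------------
# master-plot (time-temperature superposition) extrapolation
# ---------------------------------------------------------------------------

def _overlap_mse(shift, x_spec, y_spec, x_ref, y_ref):
    """MSE between the shifted spectrum and reference on shared log-f support."""
    xs = x_spec + shift
    lo = max(xs.min(), x_ref.min())
    hi = min(xs.max(), x_ref.max())
    if hi - lo < 1.0:  # require at least one shared decade
        return None
    grid = np.linspace(lo, hi, 200)
    return float(np.mean((np.interp(grid, xs, y_spec) - np.interp(grid, x_ref, y_ref)) ** 2))


def masterplot_extrapolate(
    specs_below_tg: Sequence[DielectricSpectrum],
    reference: SpectrumFit,
    shift_resolution: float = 0.01,
) -> list[tuple[float, float]]:
    """Extrapolate tau_alpha below T_g by horizontal master-plot shifting.

    Each below-T_g spectrum, peak-normalized on log-f axes, is shifted
    horizontally to superpose on the normalized alpha loss of the reference
    fit; the optimal decade shift ``s`` (grid search at ``shift_resolution``
    then parabolic refinement) gives ``tau(T) = tau_ref * 10^s``.  Shifts are
    searched over ``s >= -1``: a spectrum below T_g can only be slower than
    the above-T_g reference, with one decade of slack for noise.  Raises
    :class:`DataError` when no admissible shift yields a shared decade.
    """
    alpha = reference.mode("alpha")
    if alpha is None:
        raise FitError("reference fit has no resolved alpha mode")
    tau_ref = tau_alpha_from_hn(alpha)

    # reference normalized curve from the fitted alpha mode over a wide grid
    f_ref = np.logspace(-8, 10, 1200)
    y_ref = hn_loss(f_ref, [alpha])
    y_ref = y_ref / y_ref.max()
    x_ref = np.log10(f_ref)

    out = []
    for spec in specs_below_tg:
        spec = spec.cleaned()
        y = spec.eps_imag / spec.eps_imag.max()
        x = np.log10(spec.freq)
        lo_s = max(-1.0, x_ref.min() - x.max() + 1.0)
        hi_s = x_ref.max() - x.min() - 1.0
        if hi_s < lo_s:
            raise DataError("no admissible shift gives overlapping frequency support")
        shifts = np.arange(lo_s, hi_s + shift_resolution, shift_resolution)
        mses = np.array(
            [m if (m := _overlap_mse(s, x, y, x_ref, y_ref)) is not None else np.inf
             for s in shifts]
        )
        if not np.isfinite(mses).any():
            raise DataError("no shift gives overlapping frequency support")
        k = int(np.argmin(mses))
        s_best = shifts[k]
        if 0 < k < len(shifts) - 1 and np.isfinite(mses[k - 1]) and np.isfinite(mses[k + 1]):
            denom = mses[k - 1] - 2 * mses[k] + mses[k + 1]
            if denom > 0:
                s_best += shift_resolution * 0.5 * (mses[k - 1] - mses[k + 1]) / denom
        # shifting the spectrum up in frequency by s decades means its peak sat
        # s decades below the reference: tau(T) = tau_ref * 10^s
        out.append((float(spec.temperature), float(tau_ref * 10.0**s_best)))
    return out
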