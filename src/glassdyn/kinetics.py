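"""Crystallization-stability kinetics summaries.

Long-term storage trends (cold-crystallization onset and glass fraction vs
storage time), nucleation-assay probabilities with exact binomial intervals,
and polarized-light-microscopy radial growth-rate statistics with an
optional two-population Gaussian-mixture split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture

from .errors import DataError, DomainError, FitError

__all__ = [
    "StorageSeries",
    "StorageTrend",
    "NucleationAssay",
    "GrowthTrack",
    "GrowthRateSummary",
    "GrowthRateEstimator",
    "nucleation_summary",
    "growth_rates",
    "storage_trend",
    "growth_rate_ttest",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class StorageSeries:
    """Feature trajectory of one sample at one storage temperature."""

    sample: str
    storage_temp: float  # degC
    days: np.ndarray
    t_onset: np.ndarray  # degC of cold crystallization
    enthalpy: np.ndarray  # J/g
    glass_fraction: np.ndarray

    def __post_init__(self):
        self.days = np.asarray(self.days, dtype=float)
        self.t_onset = np.asarray(self.t_onset, dtype=float)
        self.enthalpy = np.asarray(self.enthalpy, dtype=float)
        self.glass_fraction = np.asarray(self.glass_fraction, dtype=float)
        if np.any(self.days < 0) or np.any(np.diff(self.days) <= 0):
            raise DataError("storage days must be nonnegative and increasing")
        for arr in (self.t_onset, self.enthalpy, self.glass_fraction):
            if arr.size != self.days.size:
                raise DataError("all storage-series columns must have equal length")


@dataclass(frozen=True)
class StorageTrend:
    """Linear trend of the cold-crystallization onset plus the day the glass
    fraction first crosses one half (None if never crossed)."""

    slope_t_onset_per_day: float
    se_slope: float
    t50_days: Optional[float]


@dataclass(frozen=True)
class NucleationAssay:
    """Summary of a crystallization-probability annealing assay."""

    ta: float  # annealing temperature, degC
    n_total: int
    n_crystallized: int
    probability: float
    ci95: tuple[float, float]  # Clopper-Pearson
    enthalpy_mean: float
    enthalpy_sd: float
    t_onset_mean: float
    t_onset_sd: float

    def __post_init__(self):
        if not 0 <= self.n_crystallized <= self.n_total:
            raise DomainError("require 0 <= n_crystallized <= n_total")


@dataclass
class GrowthTrack:
    """Radius-vs-time track along one radial direction of a growing crystal."""

    direction: int  # 1..16
    time_s: np.ndarray
    radius_um: np.ndarray

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.radius_um = np.asarray(self.radius_um, dtype=float)
        if self.time_s.size < 2:
            raise DataError("a growth track needs >= 2 points")
        if self.time_s.size != self.radius_um.size:
            raise DataError("time and radius must have equal length")

    @property
    def nondecreasing(self) -> bool:
        return bool(np.all(np.diff(self.radius_um) >= -1e-9))


@dataclass(frozen=True)
class MixtureSplit:
    means: tuple[float, float]
    weights: tuple[float, float]
    sigma: float
    delta_aicc: float  # AICc(1 comp) - AICc(2 comp); > 0 favors the split


@dataclass
class GrowthRateSummary:
    rates: dict[int, float]  # direction -> um/s
    mean: float
    sd: float  # sample sd (n-1)
    rejected: list[int] = field(default_factory=list)
    mixture: Optional[MixtureSplit] = None


# ---------------------------------------------------------------------------
# nucleation assay
# ---------------------------------------------------------------------------

def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial (Clopper–Pearson) confidence interval for k/n."""
    if not 0 <= k <= n or n < 1:
        raise DomainError("require 0 <= k <= n, n >= 1")
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def nucleation_summary(
    crystallized: Sequence[bool],
    enthalpy: Sequence[float] | None = None,
    t_onset: Sequence[float] | None = None,
    ta: float = float("nan"),
) -> NucleationAssay:
    """Summarize a per-sample crystallization assay at one annealing temperature.

    Probability is the exact fraction crystallized; enthalpy and onset
    statistics (sample mean ± sd) run over the crystallized samples only,
    since the features do not exist for samples that stayed amorphous.
    """
    flags = np.asarray(crystallized, dtype=bool)
    n = flags.size
    if n < 1:
        raise DataError("assay needs >= 1 sample")
    k = int(flags.sum())

    def _stats(vals):
        if vals is None or k == 0:
            return float("nan"), float("nan")
        v = np.asarray(vals, dtype=float)[flags]
        sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
        return float(np.mean(v)), sd

    e_mean, e_sd = _stats(enthalpy)
    o_mean, o_sd = _stats(t_onset)
    return NucleationAssay(
        ta=float(ta), n_total=n, n_crystallized=k, probability=k / n,
        ci95=clopper_pearson(k, n),
        enthalpy_mean=e_mean, enthalpy_sd=e_sd,
        t_onset_mean=o_mean, t_onset_sd=o_sd,
    )


# ---------------------------------------------------------------------------
# growth rates
# ---------------------------------------------------------------------------

class GrowthRateEstimator(BaseEstimator):
    """Per-direction linear growth rates with an optional bimodal split.

    ``fit(X)`` takes a sequence of :class:`GrowthTrack`; each direction's
    rate is the least-squares slope of radius vs time (invariant to a shift
    of the time origin).  Tracks with decreasing radius are rejected with a
    warning.  A two-component equal-variance (tied) Gaussian mixture with 10
    restarts is reported only when it improves the small-sample-corrected
    AIC over a single component — 16 directions is too few for an
    uncorrected criterion.

    Attributes
    ----------
    rates_ : dict direction -> rate (um/s)
    mean_, sd_ : summary statistics (sample sd)
    mixture_ : :class:`MixtureSplit` or None
    result_ : :class:`GrowthRateSummary`
    """

    def __init__(self, random_state=0, try_mixture=True):
        self.random_state = random_state
        self.try_mixture = try_mixture

    def fit(self, X, y=None):
        tracks = list(X)
        if not tracks:
            raise FitError("no growth tracks supplied")
        rates, rejected = {}, []
        for tr in tracks:
            if not tr.nondecreasing:
                rejected.append(tr.direction)
                warnings.warn(
                    f"track {tr.direction}: radius decreases; rejected", stacklevel=2
                )
                continue
            slope = np.polyfit(tr.time_s, tr.radius_um, 1)[0]
            rates[tr.direction] = float(slope)
        if not rates:
            raise FitError("all growth tracks were rejected")

        vals = np.array(list(rates.values()))
        self.rates_ = rates
        self.mean_ = float(np.mean(vals))
        self.sd_ = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        self.mixture_ = self._mixture_split(vals) if self.try_mixture else None
        self.result_ = GrowthRateSummary(
            rates=rates, mean=self.mean_, sd=self.sd_, rejected=rejected,
            mixture=self.mixture_,
        )
        return self

    def _mixture_split(self, vals: np.ndarray) -> Optional[MixtureSplit]:
        n = vals.size
        if n < 6:
            return None
        Xc = vals.reshape(-1, 1)

        def aicc(gm, k_params):
            ll = gm.score(Xc) * n
            aic = 2 * k_params - 2 * ll
            if n - k_params - 1 <= 0:
                return np.inf
            return aic + 2 * k_params * (k_params + 1) / (n - k_params - 1)

        gm1 = GaussianMixture(1, random_state=self.random_state).fit(Xc)
        gm2 = GaussianMixture(
            2, covariance_type="tied", n_init=10, random_state=self.random_state
        ).fit(Xc)
        delta = aicc(gm1, 2) - aicc(gm2, 4)
        if delta <= 0:
            return None
        order = np.argsort(gm2.means_.ravel())
        means = tuple(float(m) for m in gm2.means_.ravel()[order])
        weights = tuple(float(w) for w in gm2.weights_[order])
        return MixtureSplit(
            means=means, weights=weights,
            sigma=float(np.sqrt(gm2.covariances_.ravel()[0])), delta_aicc=float(delta),
        )


def growth_rates(tracks: Sequence[GrowthTrack], random_state: int = 0) -> GrowthRateSummary:
    """Per-direction growth rates (um/s) + mean, sd and optional bimodal split."""
    return GrowthRateEstimator(random_state=random_state).fit(tracks).result_


def growth_rate_ttest(rates_a: Sequence[float], rates_b: Sequence[float]):
    """Welch two-sample t-test between two growth-rate sets (descriptive only)."""
    return stats.ttest_ind(np.asarray(rates_a), np.asarray(rates_b), equal_var=False)


# ---------------------------------------------------------------------------
# storage trends
# ---------------------------------------------------------------------------

def storage_trend(series: StorageSeries) -> StorageTrend:
    """Monotone summaries of a storage series.

    Onset drift is the OLS slope of T_onset against storage day (degC/day,
    with its standard error); the day the glass fraction first crosses 0.5
    is linearly interpolated, or None if never crossed.
    """
    d = series.days
    if d.size < 2:
        raise FitError("storage trend needs >= 2 points")
    A = np.column_stack([np.ones_like(d), d])
    coef, *_ = np.linalg.lstsq(A, series.t_onset, rcond=None)
    resid = series.t_onset - A @ coef
    if d.size > 2:
        s2 = float(resid @ resid) / (d.size - 2)
        se = float(np.sqrt(s2 / np.sum((d - d.mean()) ** 2)))
    else:
        se = 0.0

    gf = series.glass_fraction
    t50 = None
    below = np.flatnonzero(gf <= 0.5)
    if below.size and below[0] > 0:
        i = below[0]
        frac = (gf[i - 1] - 0.5) / (gf[i - 1] - gf[i])
        t50 = float(d[i - 1] + frac * (d[i] - d[i - 1]))
    elif below.size and below[0] == 0:
        t50 = float(d[0])
    return StorageTrend(
        slope_t_onset_per_day=float(coef[1]), se_slope=se, t50_days=t50
    )
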