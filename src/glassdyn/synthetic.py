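"""Seeded synthetic-data generators with serialized ground truth.

Every generator emulates one instrument-table input class — dielectric loss
spectra across temperature, DSC thermograms, enthalpy-recovery tables, and
radial crystal-growth tracks — from a fully known parameter set, so every
fitting routine in the package can be tested as an analysis∘generation
identity.  Noise models: multiplicative Gaussian on dielectric loss
(instrument-like relative error), additive Gaussian on calorimetric signals;
all draws go through ``numpy.random.default_rng(seed)`` and regeneration
with the same seed is bit-identical.  The generating parameters (including
the seed) are returned alongside the data as a :class:`GroundTruth` that
round-trips through JSON.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .bds import DielectricSpectrum
from .dsc import EnthalpyRecoverySeries, Thermogram
from .errors import DomainError
from .kinetics import GrowthTrack
from .kww import kww_normalized_shape
from .models import arrhenius_tau, hn_complex_permittivity, kww_decay, vft_tau
from .parameters import HNMode, VFTFit

__all__ = [
    "GroundTruth",
    "SyntheticProcess",
    "gen_dielectric_series",
    "gen_kww_alpha_peak",
    "gen_enthalpy_recovery",
    "gen_thermogram",
    "gen_growth_tracks",
]


@dataclass(frozen=True)
class GroundTruth:
    """Full generating parameter set of a synthetic dataset."""

    generator: str
    params: dict
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {"generator": self.generator, "params": self.params, "seed": self.seed},
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, s: str) -> "GroundTruth":
        d = json.loads(s)
        return cls(generator=d["generator"], params=d["params"], seed=d["seed"])


@dataclass(frozen=True)
class SyntheticProcess:
    """One relaxation process: a mode shape plus a temperature law.

    ``law`` is ``("arrhenius", tau0_s, ea_kj_mol)`` or
    ``("vft", log10_tau_inf, D, T0)``.
    """

    label: str
    delta_eps: float
    a: float
    law: tuple
    b: float = 1.0

    def tau(self, T: float) -> float:
        kind = self.law[0]
        if kind == "arrhenius":
            return float(arrhenius_tau(T, self.law[1], self.law[2]))
        if kind == "vft":
            fit = VFTFit(log10_tau_inf=self.law[1], D=self.law[2], T0=self.law[3])
            return float(vft_tau(T, fit))
        raise DomainError(f"unknown temperature law {kind!r}")

    def mode(self, T: float) -> HNMode:
        return HNMode(delta_eps=self.delta_eps, tau_hn=self.tau(T),
                      a=self.a, b=self.b, label=self.label)


def _params_dict(**kw):
    out = {}
    for k, v in kw.items():
        if isinstance(v, np.ndarray):
            v = v.tolist()
        out[k] = v
    return out


def gen_dielectric_series(
    processes: Sequence[SyntheticProcess],
    T_grid: np.ndarray,
    f_grid: np.ndarray | None = None,
    noise: float = 0.02,
    eps_inf: float = 3.0,
    seed: int = 1,
    sample: str = "synthetic",
):
    """Dielectric spectra over a temperature grid from known processes.

    The loss at each temperature is the exact HN/CC sum multiplied by
    ``(1 + noise * N(0,1))`` per point; eps' comes from the same complex
    evaluation (noise-free).  Emits a warning when a process's peak stays
    outside the frequency window at every temperature (unobservable).

    Returns ``(list[DielectricSpectrum], GroundTruth)``.
    """
    if noise < 0:
        raise DomainError("noise must be >= 0")
    if f_grid is None:
        f_grid = np.logspace(-2, 7, 91)  # 10 points/decade over the usual window
    T_grid = np.asarray(T_grid, dtype=float)
    rng = np.random.default_rng(seed)

    for p in processes:
        f_pk = np.array([1.0 / (2 * np.pi * p.tau(T)) for T in T_grid])
        if np.all((f_pk < f_grid.min()) | (f_pk > f_grid.max())):
            warnings.warn(
                f"process {p.label!r}: loss peak outside the frequency window "
                "at every temperature (unobservable)", stacklevel=2,
            )

    specs = []
    for T in T_grid:
        modes = [p.mode(T) for p in processes]
        eps = hn_complex_permittivity(f_grid, modes, eps_inf=eps_inf)
        loss = -eps.imag
        if noise > 0:
            loss = loss * (1.0 + noise * rng.standard_normal(loss.shape))
        specs.append(DielectricSpectrum(
            temperature=float(T), freq=f_grid.copy(), eps_real=eps.real.copy(),
            eps_imag=loss, sample=sample,
        ))
    truth = GroundTruth(
        generator="gen_dielectric_series",
        params=_params_dict(
            processes=[
                {"label": p.label, "delta_eps": p.delta_eps, "a": p.a, "b": p.b,
                 "law": list(p.law)}
                for p in processes
            ],
            T_grid=T_grid, f_grid=f_grid, noise=noise, eps_inf=eps_inf, sample=sample,
        ),
        seed=seed,
    )
    return specs, truth


def gen_kww_alpha_peak(
    beta: float,
    f_max_hz: float = 1e3,
    temperature: float = 341.15,
    noise: float = 0.01,
    n_decades: float = 4.0,
    points_per_decade: int = 10,
    seed: int = 1,
):
    """Normalized alpha loss peak generated from the numeric KWW transform.

    The peak-normalized KWW loss shape at the requested stretching exponent
    is placed with its maximum at ``f_max_hz``, sampled over ``n_decades``
    centred on the peak, and multiplied by ``(1 + noise*N(0,1))``.

    Returns ``(DielectricSpectrum, GroundTruth)``.
    """
    xg, yg = kww_normalized_shape(beta)
    half = n_decades / 2.0
    x = np.linspace(-half, half, int(n_decades * points_per_decade) + 1)
    y = np.interp(x, xg, yg)
    rng = np.random.default_rng(seed)
    if noise > 0:
        y = y * (1.0 + noise * rng.standard_normal(y.shape))
    f = f_max_hz * 10.0**x
    spec = DielectricSpectrum(
        temperature=temperature, freq=f, eps_real=np.zeros_like(f), eps_imag=y,
        sample="kww-alpha",
    )
    truth = GroundTruth(
        generator="gen_kww_alpha_peak",
        params=_params_dict(beta=beta, f_max_hz=f_max_hz, noise=noise,
                            n_decades=n_decades, points_per_decade=points_per_decade),
        seed=seed,
    )
    return spec, truth


def gen_enthalpy_recovery(
    tau_min: float,
    beta: float,
    dh_inf: float,
    t_grid_min: np.ndarray,
    noise: float = 0.03,
    ta: float = 35.0,
    seed: int = 1,
):
    """Enthalpy-recovery table from a KWW decay with known (tau, beta).

    ``dH_t = dH_inf * (1 - Phi(t)) + N(0, noise * dH_inf)`` truncated to
    ``[0, dH_inf]`` — physically, recovery can neither be negative nor
    exceed the equilibrium excess enthalpy.

    Returns ``(EnthalpyRecoverySeries, GroundTruth)``.
    """
    t = np.asarray(t_grid_min, dtype=float)
    rng = np.random.default_rng(seed)
    dh = dh_inf * (1.0 - kww_decay(t, tau_min, beta))
    if noise > 0:
        dh = dh + noise * dh_inf * rng.standard_normal(dh.shape)
    dh = np.clip(dh, 0.0, dh_inf)
    series = EnthalpyRecoverySeries(ta=ta, t_min=t, dh=dh, dh_inf=dh_inf)
    truth = GroundTruth(
        generator="gen_enthalpy_recovery",
        params=_params_dict(tau_min=tau_min, beta=beta, dh_inf=dh_inf,
                            t_grid_min=t, noise=noise, ta=ta),
        seed=seed,
    )
    return series, truth


def gen_thermogram(
    t_lo: float = 20.0,
    t_hi: float = 180.0,
    n_points: int = 1601,
    scan_rate: float = 10.0,
    exo_up: bool = True,
    baseline: tuple[float, float] = (0.0, 0.0),
    glass_step: tuple[float, float, float] | None = (55.2, 0.45, 4.0),
    exotherm: tuple[float, float, float] | None = None,
    endotherms: Sequence[tuple[float, float, float]] = (),
    noise: float = 0.0,
    seed: int = 1,
    channel: str = "total",
    sample: str = "synthetic",
):
    """DSC heating trace composed of a glass step, an exotherm and endotherms.

    Parameters
    ----------
    glass_step : (tg_mid_degC, delta_cp_J_per_gK, width_degC) or None
        Logistic heat-capacity step.  ``width`` is the tangent-construction
        onset-to-end width (4x the logistic scale), so a noiseless
        round-trip through the detector recovers it by construction.
    exotherm : (center_degC, area_J_per_g, sigma_degC) or None
        Gaussian cold-crystallization peak.
    endotherms : sequence of (center_degC, area_J_per_g, half_width_degC)
        Lorentzian melting peaks.
    noise : additive Gaussian sd in W/g.

    Overlapping features closer than their widths trigger a warning.
    Returns ``(Thermogram, GroundTruth)``.
    """
    T = np.linspace(t_lo, t_hi, n_points)
    beta_s = scan_rate / 60.0
    endo_hf = baseline[0] + baseline[1] * T

    centers_widths = []
    if glass_step is not None:
        tg_mid, dcp, width = glass_step
        w = width / 4.0
        endo_hf = endo_hf + dcp * beta_s / (1.0 + np.exp(-(T - tg_mid) / w))
        centers_widths.append((tg_mid, width))
    if exotherm is not None:
        c, area, sig = exotherm
        endo_hf = endo_hf - area * beta_s / (sig * np.sqrt(2 * np.pi)) * np.exp(
            -0.5 * ((T - c) / sig) ** 2
        )
        centers_widths.append((c, 4 * sig))
    for c, area, hw in endotherms:
        # Lorentzian with unit area: (hw/pi) / ((T-c)^2 + hw^2)
        endo_hf = endo_hf + area * beta_s * hw / np.pi / ((T - c) ** 2 + hw**2)
        centers_widths.append((c, 2 * hw))

    for i in range(len(centers_widths)):
        for j in range(i + 1, len(centers_widths)):
            (c1, w1), (c2, w2) = centers_widths[i], centers_widths[j]
            if abs(c1 - c2) < 0.5 * (w1 + w2):
                warnings.warn(
                    f"features at {c1:.1f} and {c2:.1f} degC overlap within their widths",
                    stacklevel=2,
                )

    rng = np.random.default_rng(seed)
    if noise > 0:
        endo_hf = endo_hf + noise * rng.standard_normal(endo_hf.shape)
    hf = -endo_hf if exo_up else endo_hf
    trace = Thermogram(temperature=T, heat_flow=hf, channel=channel,
                       scan_rate=scan_rate, exo_up=exo_up, sample=sample)
    truth = GroundTruth(
        generator="gen_thermogram",
        params=_params_dict(
            t_lo=t_lo, t_hi=t_hi, n_points=n_points, scan_rate=scan_rate,
            exo_up=exo_up, baseline=list(baseline),
            glass_step=list(glass_step) if glass_step else None,
            exotherm=list(exotherm) if exotherm else None,
            endotherms=[list(e) for e in endotherms], noise=noise, sample=sample,
        ),
        seed=seed,
    )
    return trace, truth


def gen_growth_tracks(
    rates,
    n_directions: int = 16,
    duration_s: float = 60.0,
    n_samples: int = 7,
    jitter_um: float = 0.0,
    seed: int = 1,
):
    """Linear radial growth tracks with optional jitter.

    ``rates`` is a scalar (all directions equal), a length-``n_directions``
    sequence, or a two-population tuple ``((rate1, rate2), (n1, n2))`` with
    ``n1 + n2 == n_directions``.  Radii are ``rate*t + N(0, jitter)``,
    floored at zero and made nondecreasing by a running maximum (a crystal
    front never retreats).

    Returns ``(list[GrowthTrack], GroundTruth)``.
    """
    if np.isscalar(rates):
        rate_list = [float(rates)] * n_directions
    elif (isinstance(rates, tuple) and len(rates) == 2
          and isinstance(rates[0], (tuple, list)) and isinstance(rates[1], (tuple, list))):
        (r1, r2), (n1, n2) = rates
        if n1 + n2 != n_directions:
            raise DomainError("two-population counts must sum to n_directions")
        rate_list = [float(r1)] * n1 + [float(r2)] * n2
    else:
        rate_list = [float(r) for r in rates]
        if len(rate_list) != n_directions:
            raise DomainError("need one rate per direction")

    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, duration_s, n_samples)
    tracks = []
    for i, rate in enumerate(rate_list, start=1):
        r = rate * t
        if jitter_um > 0:
            r = r + jitter_um * rng.standard_normal(r.shape)
        r = np.maximum.accumulate(np.maximum(r, 0.0))
        tracks.append(GrowthTrack(direction=i, time_s=t.copy(), radius_um=r))
    truth = GroundTruth(
        generator="gen_growth_tracks",
        params=_params_dict(rates=rate_list, n_directions=n_directions,
                            duration_s=duration_s, n_samples=n_samples,
                            jitter_um=jitter_um),
        seed=seed,
    )
    return tracks, truth
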