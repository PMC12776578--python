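"""Parameter containers for the relaxation models.

All containers are frozen dataclasses validated on construction.  Internal
unit convention: seconds, Kelvin, SI heat capacities (J/(kg·K)) — with the
single deliberate exception of :class:`KWWFit`, whose time unit is declared
by the caller because the reduced quantity ``tau**beta`` is not covariant
under a change of time unit when ``beta`` varies between conditions (the
enthalpy-recovery tables are conventionally reported with tau in minutes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import DomainError

#: Boltzmann constant, J/K
K_BOLTZMANN = 1.380649e-23
#: Gas constant, J/(mol K)
R_GAS = 8.314
#: Vacuum permittivity, F/m
EPS0 = 8.8541878128e-12

_PROCESS_LABELS = ("alpha", "beta", "gamma", "delta")


@dataclass(frozen=True)
class HNMode:
    """One Havriliak–Negami relaxation mode.

    The complex-permittivity contribution is ``delta_eps / (1 + (i w tau)^a)^b``.
    A Cole–Cole mode is the symmetric special case ``b == 1``.

    Parameters
    ----------
    delta_eps : float
        Relaxation strength (dimensionless), > 0.
    tau_hn : float
        HN relaxation time in seconds, > 0.
    a, b : float
        Broadening and asymmetry exponents, each in (0, 1].
    label : str
        Process name: one of ``alpha``, ``beta``, ``gamma``, ``delta``.
    """

    delta_eps: float
    tau_hn: float
    a: float = 1.0
    b: float = 1.0
    label: str = "alpha"

    def __post_init__(self):
        if not self.delta_eps > 0:
            raise DomainError(f"delta_eps must be > 0, got {self.delta_eps}")
        if not self.tau_hn > 0:
            raise DomainError(f"tau_hn must be > 0, got {self.tau_hn}")
        if not 0 < self.a <= 1:
            raise DomainError(f"shape exponent a must be in (0, 1], got {self.a}")
        if not 0 < self.b <= 1:
            raise DomainError(f"shape exponent b must be in (0, 1], got {self.b}")
        if self.label not in _PROCESS_LABELS:
            raise DomainError(f"label must be one of {_PROCESS_LABELS}, got {self.label!r}")

    @property
    def is_cole_cole(self) -> bool:
        return self.b == 1.0


@dataclass(frozen=True)
class VFTFit:
    """Vogel–Fulcher–Tammann parameters: ``tau = tau_inf * exp(D*T0/(T-T0))``.

    Parameters
    ----------
    log10_tau_inf : float
        Decadic log of the pre-exponential time (tau_inf in seconds).
    D : float
        Angell strength parameter (dimensionless), > 0.
    T0 : float
        Vogel temperature in Kelvin, > 0.
    tg_tau : float
        The relaxation time conventionally defining T_g, default 100 s.
    """

    log10_tau_inf: float
    D: float
    T0: float
    tg_tau: float = 100.0

    def __post_init__(self):
        if not self.T0 > 0:
            raise DomainError(f"T0 must be > 0 K, got {self.T0}")
        if not self.D > 0:
            raise DomainError(f"D must be > 0, got {self.D}")
        if not self.tg_tau > 0:
            raise DomainError(f"tg_tau must be > 0, got {self.tg_tau}")

    @property
    def tau_inf(self) -> float:
        return 10.0 ** self.log10_tau_inf


@dataclass(frozen=True)
class ArrheniusFit:
    """Result of an ordinary least-squares Arrhenius fit ``ln q = ln A + Ea/(R T)``.

    ``ea`` is in kJ/mol; ``ln_prefactor`` carries the unit of the fitted
    quantity (unit scaling shifts only the intercept, never the slope).
    """

    ea: float
    ln_prefactor: float
    se_ea: float
    n_points: int

    def __post_init__(self):
        if self.n_points < 2:
            raise DomainError("an Arrhenius fit needs at least 2 points")
        if self.se_ea < 0:
            raise DomainError("se_ea must be >= 0")


@dataclass(frozen=True)
class KWWFit:
    """Stretched-exponential fit ``Phi = exp(-(t/tau)^beta)``.

    ``tau_unit`` records the caller-declared time unit of ``tau_alpha``;
    ``tau_beta`` (the decoupling quantity ``tau**beta``) is recomputed, never
    stored independently.
    """

    tau_alpha: float
    beta_kww: float
    tau_unit: str = "s"

    def __post_init__(self):
        if not self.tau_alpha > 0:
            raise DomainError(f"tau_alpha must be > 0, got {self.tau_alpha}")
        if not 0 < self.beta_kww <= 1:
            raise DomainError(f"beta_kww must be in (0, 1], got {self.beta_kww}")

    @property
    def tau_beta(self) -> float:
        """``tau_alpha ** beta_kww`` in the declared unit."""
        return self.tau_alpha ** self.beta_kww


@dataclass(frozen=True)
class CMParams:
    """Coupling-Model parameters for the primitive/JG relaxation time.

    ``tc`` is the crossover time (2 ps by convention); ``n = 1 - beta_kww``
    is the coupling parameter.
    """

    n: float
    tc: float = 2e-12

    def __post_init__(self):
        if not 0 <= self.n < 1:
            raise DomainError(f"coupling parameter n must be in [0, 1), got {self.n}")
        if not self.tc > 0:
            raise DomainError(f"tc must be > 0, got {self.tc}")

    @classmethod
    def from_beta(cls, beta_kww: float, tc: float = 2e-12) -> "CMParams":
        return cls(n=1.0 - beta_kww, tc=tc)


@dataclass(frozen=True)
class CRRInputs:
    """SI-unit inputs for the Donth estimate of the cooperativity length.

    Parameters
    ----------
    tg_onset : float
        Onset glass-transition temperature, K.
    half_width : float
        Half the glass-transition width (onset to end), K.
    rho : float
        Density, kg/m^3.
    cpg, cpl : float
        Specific heat of glass / supercooled liquid, J/(kg·K); cpl > cpg.
    """

    tg_onset: float
    half_width: float
    rho: float
    cpg: float
    cpl: float

    def __post_init__(self):
        if not self.half_width > 0:
            raise DomainError("half_width must be > 0")
        if not self.rho > 0:
            raise DomainError("rho must be > 0")
        if not 0 < self.cpg < self.cpl:
            raise DomainError("require cpl > cpg > 0 (no heat-capacity contrast otherwise)")
        if not self.tg_onset > 0:
            raise DomainError("tg_onset must be > 0 K")


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + 273.15


def kelvin_to_celsius(t_k: float) -> float:
    return t_k - 273.15
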