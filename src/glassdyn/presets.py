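"""Named fixture presets: measured parameters of celecoxib (CEL) glass and
its 2% / 5% PVPVA mixtures.

These are the reported experimental values for the three compositions —
midpoint T_g, VFT parameters (pre-exponential fixed at log10 tau_inf = -14),
the alpha-peak KWW stretching exponent, activation energies of the
beta/gamma/delta secondary relaxations, the enthalpy-recovery KWW table
(tau in minutes), heat capacities and density for the cooperativity length,
the melting temperatures of Forms III and I, and the radial growth-rate
statistics at 120 degC.  Secondary-process attempt times and relaxation
strengths are not reported; the preset ships physically typical choices
(attempt times of order 1e-14–1e-17 s, strengths well below the alpha
strength) so the synthetic spectra land inside the 1e-2–1e7 Hz window at the
measured temperatures.
"""

from __future__ import annotations

from .parameters import VFTFit
from .synthetic import SyntheticProcess

#: gamma-process attempt time used throughout the synthetic series, seconds
GAMMA_TAU0_S = 1e-16

PRESETS: dict[str, dict] = {
    "cel-pure": {
        "tg_mid_C": 55.2,
        "vft": {"log10_tau_inf": -14.0, "D": 6.33, "T0": 280.0},
        "beta_kww_alpha": 0.69,
        "secondary_ea_kj_mol": {"beta": 79.1, "gamma": 33.9, "delta": 23.9},
        "jg_ea_kj_mol": 381.0,
        "enthalpy_recovery": {  # T_a degC -> (tau_min, beta_kww)
            30.0: (27200.0, 0.50),
            35.0: (4870.0, 0.48),
            40.0: (647.0, 0.57),
            45.0: (315.0, 0.59),
        },
        "growth": {"mean_um_s": 3.08, "sd_um_s": 1.65, "bimodal": None},
    },
    "cel-pvpva2": {
        "tg_mid_C": 56.0,
        "vft": {"log10_tau_inf": -14.0, "D": 6.30, "T0": 281.0},
        "beta_kww_alpha": 0.61,
        "secondary_ea_kj_mol": {"beta": 78.9, "gamma": 46.5, "delta": 27.8},
        "jg_ea_kj_mol": 317.0,
        "enthalpy_recovery": {
            35.0: (2430.0, 0.67),
            40.0: (981.0, 0.56),
            45.0: (266.0, 0.49),
        },
        "growth": {"mean_um_s": 4.61, "sd_um_s": 2.36, "bimodal": (1.0, 5.0)},
    },
    "cel-pvpva5": {
        "tg_mid_C": 57.8,
        "vft": {"log10_tau_inf": -14.0, "D": 6.83, "T0": 279.0},
        "beta_kww_alpha": 0.58,
        "secondary_ea_kj_mol": {"beta": 72.8, "gamma": 49.4, "delta": 26.8},
        "jg_ea_kj_mol": 293.0,
        "enthalpy_recovery": {
            35.0: (1890.0, 0.87),
            40.0: (1380.0, 0.58),
            45.0: (347.0, 0.57),
        },
        "growth": {"mean_um_s": 4.61, "sd_um_s": 2.36, "bimodal": None},
    },
}

#: shared calorimetric constants of the CEL glass
CPG_J_PER_G_K = 1.62
CPL_J_PER_G_K = 2.07
DELTA_CP_J_PER_G_K = CPL_J_PER_G_K - CPG_J_PER_G_K  # 0.45
RHO_G_CM3 = 1.41
MELT_FORM3_C = 162.0
MELT_FORM1_C = 164.0


def vft_preset(name: str) -> VFTFit:
    p = PRESETS[name]["vft"]
    return VFTFit(log10_tau_inf=p["log10_tau_inf"], D=p["D"], T0=p["T0"])


def gamma_process(name: str = "cel-pure", delta_eps: float = 0.3, a: float = 0.3) -> SyntheticProcess:
    """Cole–Cole gamma-relaxation process with the preset's activation energy."""
    ea = PRESETS[name]["secondary_ea_kj_mol"]["gamma"]
    return SyntheticProcess(
        label="gamma", delta_eps=delta_eps, a=a, law=("arrhenius", GAMMA_TAU0_S, ea)
    )


def secondary_processes(name: str = "cel-pure") -> list[SyntheticProcess]:
    """beta + gamma + delta Cole–Cole processes for a composition preset.

    Attempt times and strengths are the package's typical-value choices
    (module docstring); activation energies are the measured ones.
    """
    ea = PRESETS[name]["secondary_ea_kj_mol"]
    return [
        SyntheticProcess(label="beta", delta_eps=0.15, a=0.35,
                         law=("arrhenius", 7e-18, ea["beta"])),
        SyntheticProcess(label="gamma", delta_eps=0.3, a=0.3,
                         law=("arrhenius", GAMMA_TAU0_S, ea["gamma"])),
        SyntheticProcess(label="delta", delta_eps=0.6, a=0.3,
                         law=("arrhenius", 1e-14, ea["delta"])),
    ]


def alpha_process(name: str = "cel-pure", delta_eps: float = 5.0, a: float = 0.85,
                  b: float = 0.6) -> SyntheticProcess:
    p = PRESETS[name]["vft"]
    return SyntheticProcess(
        label="alpha", delta_eps=delta_eps, a=a, b=b,
        law=("vft", p["log10_tau_inf"], p["D"], p["T0"]),
    )
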