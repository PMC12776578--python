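# glassdyn

Molecular-mobility and crystallization-stability analysis for amorphous
pharmaceutical glasses characterized by broadband dielectric spectroscopy
(BDS) and differential scanning calorimetry (DSC).

Amorphous (glassy) drugs dissolve better than their crystals but tend to
recrystallize on storage; formulators stabilize them as amorphous solid
dispersions with polymeric excipients, and diagnose the underlying molecular
mobility with BDS and DSC.  `glassdyn` implements the complete analysis
chain those measurements require, for people who work with instrument-style
tables (per-temperature loss spectra, DSC heating traces, enthalpy-recovery
tables, radial crystal-growth tracks) rather than vendor software:

- **Dielectric deconvolution** — fit loss spectra ε″(f) with sums of
  Havriliak–Negami modes, ε\*(ω) = ε∞ + Σₖ Δεₖ/[1 + (iωτ_HN)^a]^b (+ a dc
  conductivity term), with Cole–Cole (b = 1) secondary modes; convert
  τ_HN → τ_α via τ_α = τ_HN·[sin(πab/(2+2b))]^{1/a}·[sin(πa/(2+2b))]^{−1/a}.
- **Relaxation maps** — track α/β/γ/δ processes across temperature, fit the
  secondary processes with the Arrhenius law ln τ = ln τ₀ + E_a/RT and the
  α-process with the Vogel–Fulcher–Tammann law τ_α = τ∞·exp(DT₀/(T−T₀))
  (optionally pinned to τ_α(T_g) = 100 s), and extrapolate τ_α below T_g by
  master-plot (time–temperature superposition) shifting.
- **KWW analysis** — the stretched exponential Φ = exp[−(t/τ_α)^β_KWW] fits
  both calorimetric enthalpy recovery (Φ = 1 − ΔH_t/ΔH∞ with
  ΔH∞ = ΔC_p(T_g − T_a)) and, through its numeric one-sided Fourier
  transform, the shape of the normalized dielectric α-peak.
- **Coupling-Model prediction** — the primitive / Johari–Goldstein time
  τ_JG ≈ τ₀ = t_c^n·τ_α^{1−n} with n = 1 − β_KWW and t_c = 2 ps.
- **Calorimetric features** — tangent-baseline glass-transition detection
  (onset/midpoint/end, ΔC_p), the Donth cooperativity length
  L = {3kT_g²/(4πρ·ΔdT_g²)·(1/C_pg − 1/C_pl)}^{1/3}, cold-crystallization
  onset and enthalpy, two-Lorentzian melting deconvolution for polymorph
  fractions, and the remaining glass fraction from the ΔC_p decay.
- **Stability kinetics** — storage-series trends, nucleation-assay
  probabilities with exact binomial intervals, and radial growth-rate
  statistics with an optional two-population Gaussian-mixture split.
- **Synthetic data** — seeded generators for every input class with
  serialized ground truth, so each fitter is tested as an
  analysis∘generation identity.

Fit-shaped operations are scikit-learn-style estimators (`fit`, `predict`,
`get_params`, trailing-underscore attributes) — `HNSpectrumFitter`,
`VFTRegressor`, `ArrheniusRegressor`, `KWWShapeFitter`,
`EnthalpyRecoveryFitter`, `GlassTransitionDetector`, `MeltingDeconvolver`,
`GrowthRateEstimator` — with plain functions as thin wrappers.

## Worked example

Generate a synthetic γ-relaxation temperature series (the sulfonamide-ring
secondary process of celecoxib: Cole–Cole modes following an Arrhenius law
with E_a = 33.9 kJ/mol, 2% noise), deconvolute each spectrum, build the
relaxation map, and recover the activation energy; then fit an
enthalpy-recovery table and extract a glass transition:

```python
import numpy as np
from glassdyn import (HNMode, VFTFit, fit_spectrum, track_modes,
                      fit_enthalpy_recovery, vft_invert,
                      detect_glass_transition, crr_size)
from glassdyn.presets import gamma_process
from glassdyn.synthetic import (gen_dielectric_series, gen_enthalpy_recovery,
                                gen_thermogram)

specs, truth = gen_dielectric_series([gamma_process()],
                                     T_grid=np.arange(153.15, 233.16, 4.0),
                                     noise=0.02, seed=1)
fits, prev = [], None
template = [HNMode(delta_eps=0.5, tau_hn=1e-6, a=0.5, b=1.0, label="gamma")]
for spec in specs:
    fit = fit_spectrum(spec, prev if prev is not None else template)
    fits.append(fit); prev = fit
arr = track_modes(fits).arrhenius["gamma"]
print(f"gamma-process E_a = {arr.ea:.1f} +/- {arr.se_ea:.1f} kJ/mol")

series, _ = gen_enthalpy_recovery(tau_min=4870.0, beta=0.48, dh_inf=0.45*20.2,
                                  t_grid_min=np.logspace(2, np.log10(3e4), 8),
                                  noise=0.03, ta=35.0, seed=1)
kww = fit_enthalpy_recovery(series, tg=55.2, delta_cp=0.45)
print(f"KWW fit: tau = {kww.tau_alpha:.0f} min, beta = {kww.beta_kww:.2f}")

trace, _ = gen_thermogram(t_lo=20, t_hi=90, n_points=701,
                          glass_step=(55.2, 0.45, 4.0), noise=0.002, seed=1)
gt = detect_glass_transition(trace)
print(f"Tg mid = {gt.tg_mid:.1f} degC, CRR = "
      f"{crr_size(gt, rho=1.41, cpg=1.62, cpl=2.07):.2f} nm")
print(f"T(tau=100 s) = "
      f"{vft_invert(100.0, VFTFit(-14.0, 6.33, 280.0)) - 273.15:.1f} degC")
```

prints

```
gamma-process E_a = 33.9 +/- 0.1 kJ/mol
KWW fit: tau = 4737 min, beta = 0.47
Tg mid = 55.2 degC, CRR = 2.28 nm
T(tau=100 s) = 55.0 degC
```

The recovered activation energy matches the generating value (33.9 kJ/mol);
the enthalpy-recovery time comes back within 3% of the generating
τ = 4870 min at this noise level; the detected midpoint T_g equals the
generating 55.2 °C and the cooperativity length lands in the ~2 nm range
typical of organic glasses; and inverting the fitted VFT law at the
conventional τ_α = 100 s recovers the calorimetric T_g.

A command-line interface mirrors the library
(`glassdyn simulate | fit-bds | fit-enthalpy | crr | melt-deconv |
glass-fraction | growth-rates | nucleation-summary | report`); run
`glassdyn --help` for details.

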