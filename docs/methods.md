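# Methods

This note records the models, conventions, numerical choices and known
limitations of `glassdyn`, in the order the analysis usually runs.

## Models and conventions

**Units.** Seconds, Kelvin and SI heat capacities internally; conversions
happen only at the I/O boundary (files may declare `temperature_K` or
`temperature_C`; having both is an error, never a guess).  One deliberate
exception: enthalpy-recovery KWW times are fitted and reported with τ in
**minutes**, the conventional unit of such tables, because the decoupling
quantity τ^β is not covariant under a change of time unit when β varies
between conditions — the unit is recorded on every `KWWFit`.  Constants:
k = 1.380649·10⁻²³ J/K, R = 8.314 J/(mol·K), ε₀ = 8.8541878128·10⁻¹² F/m.

**Havriliak–Negami permittivity.** ε\*(ω) = ε∞ + Σₖ Δεₖ/[1+(iωτₖ)^aₖ]^bₖ −
iσ_dc/(ε₀ω^s), physics sign convention ε\* = ε′ − iε″.  Secondary modes are
Cole–Cole (b = 1).  The conductivity exponent s defaults to 1 (pure ohmic)
and σ_dc is fitted only when enabled.  The α-time conversion
τ_α = τ_HN·[sin(πab/(2+2b))]^{1/a}·[sin(πa/(2+2b))]^{−1/a} reduces exactly
to τ_HN for b = 1.

**Temperature laws.** Secondary processes: Arrhenius, E_a from the OLS
slope of ln τ (or ln τ^β) against 1/T; the intercept absorbs any unit
scaling, so only the slope is physical.  α-process: VFT,
τ = τ∞·exp(DT₀/(T−T₀)), with closed-form inverse
T = T₀(1 + D/ln(τ/τ∞)).  The pre-exponential may be fixed (the phonon-like
choice log₁₀τ∞ = −14) or fitted free; a free fit trades D and T₀ against
τ∞ and tends to unusually small pre-exponentials (≈ −16) while leaving
τ(T) essentially unchanged over the data range, so neither mode is treated
as canonical — both are supported, and a T_g constraint (τ(T_g) = 100 s)
can be enforced exactly by parameter elimination.

**Coupling Model.** τ_JG ≈ τ₀ = t_c^n·τ_α^{1−n}, n = 1 − β_KWW, t_c = 2 ps
by default; evaluated in log space.  τ_JG ≤ τ_α whenever τ_α ≥ t_c.

**Donth cooperativity length.** L = {3kT_g²/(4πρΔdT_g²)·(1/C_pg −
1/C_pl)}^{1/3} with the **onset** T_g and ΔdT_g = half the onset-to-end
transition width, SI units enforced at the boundary.  The literature notes
systematic errors in this estimate; the package reports it as the standard
comparative index (≈ 2 nm for typical organic glasses), not an absolute
size.  ΔH∞ = ΔC_p(T_g − T_a) uses C_pl − C_pg when no sample-specific ΔC_p
is supplied.

## Spectrum deconvolution

Fits minimize residuals of **log₁₀ ε″ against log₁₀ f**: the loss spans
many decades over the 10⁻²–10⁷ Hz window, and linear-space residuals would
let the α-peak drown the secondary modes.  Strengths and times are
parameterized in log₁₀; bounds 0 < a, b ≤ 1 are enforced by the trust-region
optimizer, b pinned at 1 for non-α modes.  Mode inclusion is
template-driven: the caller declares which labelled modes a window contains
and each temperature is seeded from the previous temperature's fit
(continuation), which is how a practitioner walks a temperature series.
Optimizer failure never raises — the fit returns best-effort parameters
with `converged=False`.  Non-positive loss points are dropped before
fitting (log residuals).

Cross-temperature association in `track_modes` follows **labels**, never τ
proximity, so processes whose times cross stay separate; same-temperature
modes within 0.3 decades of each other are flagged as ambiguous, and a
label present at fewer than half the temperatures is excluded with a
warning.  Identifiability caveat: three very broad overlapping Cole–Cole
modes (a ≲ 0.35) spaced ≈ 3 decades produce a nearly featureless loss and
the middle mode's τ is poorly determined at 2% noise; the multi-mode
recovery guarantees quoted in the tests hold for modes with resolvable
shoulders (a ≈ 0.5, spacing ≥ 1.5 decades).  Single-mode windows are well
behaved down to a = 0.3.

## KWW loss spectrum and α-peak shape

The dielectric loss of Φ(t) = exp[−(t/τ)^β] is the one-sided Fourier sine
transform of −dΦ/dt, which has no closed form for β < 1.  It is evaluated
with a piecewise-linear **Filon quadrature** on a 2048-point logarithmic
time grid spanning 12 decades: on each panel the smooth factor −dΦ/dt is
interpolated linearly and ∫(c₀+c₁t)sin(ωt)dt integrated exactly, which
stays accurate at ω ≫ 1/τ where an ordinary trapezoid rule under-resolves
the oscillation.  Validation: the β = 1 limit reproduces the exact Debye
loss ωτ/(1+ω²τ²) to < 0.03% across eight decades.  Peak-normalized shapes
are cached per β on a 0.01 grid.

`KWWShapeFitter` matches the measured peak, normalized as ε″/ε″max vs
f/fmax, to the cached shapes by least squares with a free amplitude and a
free sub-grid horizontal shift (these absorb the discretization of the
measured maximum); β is located by a coarse (0.05) then fine (0.01) grid
search with parabolic refinement, over β ∈ [0.2, 1].  A peak whose maximum
sits on the window edge is refused rather than extrapolated.

## Master-plot extrapolation below T_g

τ_α below T_g is estimated by time–temperature superposition: each
below-T_g spectrum, peak-normalized on log-f axes, is shifted horizontally
onto the normalized α loss of an above-T_g reference fit; the objective is
the mean squared difference on the shared log-f support (≥ 1 decade
required), minimized by grid search at 0.01 decade with parabolic
refinement, and τ(T) = τ_ref·10^s.  Shifts are searched over s ≥ −1: below
T_g the structural relaxation can only be slower than the reference, with
one decade of slack for noise.  This is a documented, self-contained TTS
procedure; it presumes the α-peak shape is temperature-independent
(thermorheological simplicity), which holds by construction for synthetic
data and approximately for real glass-formers near T_g.

## DSC feature extraction

Heat flow is stored per gram with a recorded exo-up/exo-down convention
(default exo-up) and converted internally to an endotherm-positive apparent
specific heat, heat flow divided by the heating rate, so the glass step
reads directly in J/(g·K) and peak areas integrate to J/g.

**Glass transition.** Savitzky–Golay derivative (window ≈ 1% of the
region, ≥ 5 points — narrow, so the tangent slope is not flattened);
transition zone where the derivative exceeds half its maximum; linear
pre-/post-baselines fitted outside one zone-width of padding; onset and end
from the baseline/tangent intersections; midpoint where the signal crosses
half the baseline gap; ΔC_p = baseline gap at the midpoint.  A step below
5× the pre-baseline residual noise raises a not-found error.  The
synthetic logistic step is parameterized by the tangent-construction width
(4× the logistic scale), so generator → detector round-trips exactly on
noiseless traces.

**Cold crystallization.** Peak feet from a two-pass threshold
(max(2×noise, 0.5% of peak) above an iteratively refit linear baseline);
onset from the steepest leading-edge tangent intersected with the pre-peak
baseline (for a Gaussian exotherm this lands at center − 2σ, the standard
DSC construction); enthalpy by trapezoidal integration above the baseline.
No peak above 5× noise returns `None` — a stabilized sample legitimately
shows no exotherm.  Noise is estimated robustly from first differences.

**Melting deconvolution.** Two Lorentzians A·w²/((T−c)²+w²), area πAw,
fitted on the baseline-subtracted endotherm; the higher-melting component's
area share is the Form I fraction (Form I ≈ 164 °C, Form III ≈ 162 °C for
celecoxib).  Degeneracy: the split is flagged when the centers collapse
within 0.2 °C **or** when a single Lorentzian fits within 2× the two-peak
SSE (a lone peak makes the split non-identifiable; empirically single
peaks give ratios ≈ 1.2 and genuine pairs > 5); the fraction is then 1.0
or 0.0 by which initial center the merged peak sits nearer.  Lorentzian
tails extend beyond any finite window, so absolute areas carry a few
percent truncation; the fraction is unaffected.

**Enthalpy recovery.** Φᵢ = 1 − ΔHᵢ/ΔH∞ fitted by unweighted least squares
(the tables give no replicate variances to weight by) over (log τ, β) with
β ∈ (0.05, 1]; τ initialized where Φ crosses 1/e.  Recovered enthalpies are
taken as already-integrated ΔH_t values; any Φᵢ < 0 (over-recovery) is an
error listing the offending time points, while the lower-level
`phi_from_recovery` only flags without clipping.

## Stability kinetics

Growth rates are per-direction OLS slopes of radius vs time (invariant to
the time origin); dispersion is the sample standard deviation (n−1) across
directions.  Tracks with decreasing radius are rejected with a warning.
The optional bimodal split is a two-component equal-variance Gaussian
mixture (EM, 10 restarts, fixed seed) reported only when it improves the
small-sample-corrected AIC (AICc) over one component — 16 directions is too
few for an uncorrected criterion.  Whether reported growth-rate dispersions
are per-direction or per-crystal is ambiguous in typical reports;
per-direction is used and stated.  A Welch two-sample t-test utility is
provided as descriptive output only.  Nucleation probabilities are exact
fractions k/n with Clopper–Pearson 95% intervals; feature statistics run
over crystallized samples only.

## Synthetic data

Generators emulate the four instrument-table classes with known ground
truth serialized beside the data (JSON round-trip, bit-identical under a
fixed seed).  Noise models: multiplicative Gaussian on dielectric loss
(instrument-like relative error, default 2%), additive Gaussian on
calorimetric signals (default 3% of ΔH∞ for recovery tables; 0.002 W/g for
thermograms, ≈ 1/37 of a 0.45 J/(g·K) glass step at 10 °C/min).  Generated
recovery enthalpies are truncated to [0, ΔH∞]: physically, recovery can
neither be negative nor exceed the equilibrium excess enthalpy.  The
dielectric generator warns when a process's loss peak falls outside the
frequency window at every temperature.

The composition presets carry the measured parameter sets of celecoxib
glass and its 2%/5% PVPVA mixtures (T_g, VFT parameters, β_KWW, secondary
activation energies, recovery tables, heat capacities, density, melting
centers, growth statistics).  Secondary-process attempt times and
relaxation strengths are not reported anywhere; the presets ship typical
values (τ₀ of order 10⁻¹⁴–10⁻¹⁷ s chosen so each process's peak crosses
the 10⁻²–10⁷ Hz window within the measured temperature range, strengths
well below the α strength).  Synthetic data share the fitted model's
functional form, so recovery tests demonstrate estimator correctness and
noise robustness — not robustness to model misspecification, electrode
polarization, Maxwell–Wagner contributions or baseline drift in real
measurements.

## Problem sizes and determinism

The recovery pipelines run at the sizes the assays use: dielectric series
of 21 temperatures (−120…−40 °C every 4 °C) × 91 frequencies (10/decade),
recovery tables of 8 log-spaced times over 100–30000 min, 16 growth
directions, 10 independent seeds per stochastic summary; `scripts/
acceptance.py` derives all sub-seeds from its single `--seed` argument.
Everything completes in seconds on one core.

## Known limitations

- No dielectric-modulus or conductivity-formalism analysis; no electrode
  polarization or Maxwell–Wagner modeling; no pressure dependence.
- DSC: no instrument calibration, Tzero pan corrections, or deconvolution
  of raw modulated heat flow into reversing/nonreversing channels (the
  channels are accepted as inputs).
- Enthalpies are per gram of total mixture mass; no per-drug normalization.
- Image analysis of micrographs is out of scope — growth radii are assumed
  digitized upstream.
- The Donth length and the Coupling-Model prediction are model-based
  estimates whose absolute accuracy is debated; they are reported for
  comparison across compositions, not as certified sizes or times.
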