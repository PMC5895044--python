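# Methods

## Scope

`frrphys` implements the computational chain of a batch N-starvation /
nitrate-resupply photophysiology experiment: FRRf transient simulation and
fitting, derivation of the PSII photophysiological parameter set, pigment
stoichiometry, and growth/recovery scoring, exercised end-to-end on
synthetic species scenarios. Wet-lab concerns (culturing, HPLC
chromatography, CHN instrumentation, nutrient chemistry) and biological
interpretation are out of scope; dark-acclimation periods are configuration,
not modelled.

## FRRf forward model

Induction follows the connected-units model: with closed PSII fraction *C*,
flashlet excitation rate *i* (quanta Å⁻² µs⁻¹) and cross-section σ,
dC/dt = iσ(1−C)/(1−ρC), observed through
F(C) = Fo + (Fm−Fo)·C(1−ρ)/(1−ρC). Separating variables gives
−(1−ρ)ln(1−C) + ρC = σs (s = cumulative dose), solved in closed form with
the principal Lambert W branch. Simulation and fitting therefore share the
exact continuous-time integral — there is no Euler step error, and the ρ→0
limit reduces to the saturating exponential 1−e^(−σs) exactly (both are
property-tested against an independent ODE integration).

Fluorescence is evaluated at the end of each flashlet (dose k·φ after k
flashlets, φ = intensity × duration). Reopening during the 128 µs
induction window is neglected: the shortest reopening lifetime in any
scenario (400 µs) is ~3× the window, and the generator makes the same
assumption, so the approximation is part of the model rather than an error
source. The default excitation intensity (2.0833×10⁻⁴ quanta Å⁻² µs⁻¹,
i.e. φ = 2.5×10⁻⁴ quanta Å⁻²) is an instrument-calibration scalar chosen so
a typical σ ≈ 500 Å² quanta⁻¹ saturates the 40-flashlet train; fitted σ is
reported in Å² quanta⁻¹ under this calibration and scales inversely with φ
if recalibrated.

Relaxation: C(t) = C_end·[a₁e^(−t/τ₁) + a₂e^(−t/τ₂)] sampled every 100 µs
over 0.4 s, mapped through the same F(C). The amplitude-weighted
τ = a₁τ₁ + a₂τ₂ summarises reopening; 1/τ (s⁻¹) is the reopening rate
constant.

## Fitting

Bounded nonlinear least squares (lmfit/`leastsq`) on **log fluorescence**:
the instrument noise model is multiplicative lognormal, which log residuals
make homoscedastic. Initialisation: Fô = first point, F̂m = maximum, σ̂
from a log-linear fit to the early rise, ρ̂ = 0.3; six deterministic
restarts with perturbed (σ̂, ρ̂) guard against local minima; bounds
ρ ∈ [0, 0.99]. Failure modes are explicit: no detectable rise or
non-convergence raise a flagged error rather than returning silently.

**Estimator bias correction.** At 3% noise the raw (σ̂, ρ̂) estimates carry
a genuine second-order bias (~−0.7% in σ) from the curvature of the sloppy
σ–ρ direction. The fitter subtracts the standard curvature-based bias
approximation for nonlinear regression (computed from the numeric Jacobian
and per-point Hessians of the log model), refined by averaging the bias map
over unscented sigma points of the fit covariance — the bias map itself
curves along the valley, so evaluating it only at the noisy estimate
over-corrects on average. Residual bias is ≲0.15% in σ at 3% noise. The
correction vanishes on noiseless data (it scales with residual variance),
so exact round-trip identity fit(simulate(p)) = p is preserved. A
Monte-Carlo check (500 replicates per truth) is part of the acceptance
suite.

**Relaxation fitting** fixes Fm and ρ from the induction fit but lets the
baseline float: pinning the baseline to the induction Fô lets any small Fô
error masquerade as an unresolvably slow exponential fitted to the long
post-decay plateau (this produced order-of-magnitude τ₁ outliers in ~30% of
noisy fits before the change; with a floating baseline the weighted τ is
unbiased to +0.2% with 9% spread at 3% noise). Lifetimes are bounded by the
0.4 s observation window — slower components are not resolvable by this
protocol — and ordered slow-first after fitting; if one amplitude collapses
below 0.01 the fit degrades to a flagged single exponential.

**Light steps.** Under actinic light the recorded rise runs from the
steady-state yield Fs to Fm′ with the apparent σ′ at that light; the fitter
treats it with the same functional family as the dark rise (baseline,
maximum, rate, sigmoidicity), so the fitted "Fo" of a light step is Fs and
the fitted "Fm" is Fm′. After the 1 s dark gap a second rise from Fo′₁ₛ to
Fm′₁ₛ yields the 1 s-relaxed pair and σ′₁ₛ. The generator produces light
steps under exactly this convention; a real instrument's partially-closed
starting state is not modelled. σ′ and ρ′ are reported at low actinic
light — 21 µmol photons m⁻² s⁻¹ for diatom scenarios, 8 for prasinophytes
(configurable) — and Fs/Fm′ at the growth irradiance of 85.

## Derived parameters

Formulas as in the README. Numerical conventions:

- Φ_NO uses the dark-acclimated Fm in the denominator (Fs/Fm), not Fm′ —
  the partition then closes exactly by construction since
  Φ_NPQ = 1 − Φ_PSII − Φ_NO.
- The Fo′ estimate Fo′₁ₛ·Fm′/Fm′₁ₛ is algebraically identical to the
  correction form Fo′₁ₛ·{1 − [(Fm′₁ₛ−Fm′)/Fm′₁ₛ]}. It is exact whenever
  quenching scales Fo and Fm proportionally (as in the generator's model).
- ETR unit conversion: σ′[Å²]·10⁻²⁰ m²/Å² · I[µmol m⁻² s⁻¹] ·
  6.022×10¹⁷ quanta µmol⁻¹ · qP, covered by a dedicated unit test
  (σ′ = 500, I = 85, qP = 0.5 → 128.0 e⁻ PSII⁻¹ s⁻¹).
- Out-of-range yields and qP are flagged, never silently clipped (qP is
  clipped to [0,1] but carries a flag), so pathological fits stay visible.
- Standard errors propagate by the first-order delta method (numeric
  gradients), combined in quadrature with among-replicate SE; the
  delta-method SE for ratio-type quantities is verified against Monte-Carlo
  resampling to <5% at CV 0.05.

## Pigments

Molar masses for the 14 pigments ship as a constants table (literature
values, g mol⁻¹). Chl a:C and Chl a:N are mass:mass; pigment:pigment and
pigment:Chl a ratios are molar. "Xanthophyll-cycle pigments" means DD+DT
for diatoms and V+A+Z for prasinophytes — the natural reading for
Xanth:Chl a, adopted throughout. Dihydrolutein is an ordinary pigment
column to the pipeline (its HPLC quantification against a lutein standard
is a data-production detail). ā* = mean over 400–700 nm of
a*(λ) = ln(10)·A(λ)/(ℓ·[Chl a]); the spectral average is unweighted by
default with a lamp-spectrum-weighted variant behind a keyword, since a
growth-light-weighted average is the photophysiologically relevant
alternative.

## Growth and recovery

µ_max: OLS slope of ln N vs time. Recovery: daily rates
µ_R(d) = ln(N_d/N_{d−1})/Δt are **interval averages**, so they are placed
at interval midpoints for the regression; an exact (0, 0) anchor is
included because N-starved cultures show no growth at the moment of
resupply (their unamended controls never grow). Intervals within 10% of
µ_max count as plateau and are excluded, as is the last pre-plateau
interval (when at least two remain): the interval containing the crossing
averages ramp and plateau growth and would bias the slope low. With these
conventions the estimator recovers the generator's crossing time exactly on
noiseless data for every preset, including the failed-recovery case where
the crossing lies beyond the 5-day window (flagged extrapolation). A
flat-or-declining µ_R series that never reaches µ_max yields T_R = ∞,
RS = 0, flagged. Negative µ_R values (density declines) are retained in the
regression. RS is computed per replicate tube and then averaged, matching
how triplicate spread is reported; the percent change in RS runs early
stationary → late stationary, the convention that reproduces the printed
−19.35% exactly from RS 0.93 → 0.75.

## Synthetic scenarios

Presets (`data/presets.yaml`) encode two classes of numbers. Anchored:
µ_max (0.75/0.57/0.72/0.40 d⁻¹), per-stage recovery scores (T_R derived as
1/(RS·µ_max)), replete Chl a:C (0.051 diatoms, 0.031 prasinophytes),
replete Antenna:Chl a (1.35 Ms, 1.21 Ot), and the replete→late-stationary
per-cell Chl a change (−77.1% diatoms, −35.3% prasinophytes). Everything
else — fluorescence yields, cross-sections, connectivities, lifetimes, NPQ
amplitudes, minor-pigment ratios, densities, ā* levels — is plausible
filler interpolating the qualitative lineage patterns: rising σ′ and
shrinking PSII pools in diatoms; near-invariant σ′ with a large late
energy-dependent NPQ induction in Ot; falling σ′, sustained quenching and
steadily rising Φ_NO in Ms. These magnitudes must not be read as measured
values.

Light response of a phase state: energy-dependent NPQ follows a
Stern–Volmer saturation NPQ(I) = npq_max·I/(I+I₅₀); quenching divides Fo
and Fm by (1+NPQ), divides σ by (1+0.3·NPQ), and relaxes 40% during the
1 s gap (5% for the "locked-in" sustained mode). The steady-state closed
fraction balances closure σ′·I against reopening 1/τ. Because Fo and Fm
quench proportionally, the pipeline's Fo′ correction is exact on noiseless
data, and every derived parameter has an analytic ground-truth value — the
basis of the noiseless-equality test suite.

Noise is multiplicative lognormal with unit mean (defaults: CV 3% on
fluorescence samples and density counts, 2% on pigment/CN quotas), with a
per-replicate multiplier drawn once per replicate culture on top of
per-sample noise. All randomness derives from explicit integer seeds
through labelled substreams, so every record is reproducible.

What the generator does *not* emulate: absolute instrument counts, PSI
contamination, spectral mismatch between measuring LED and growth light,
temperature effects, the 12:12 photoperiod, partially-closed starting
states under actinic light, or nutrient chemistry beyond a declining
N-quota trajectory. Passing tests therefore demonstrate correctness of the
estimation chain under the stated noise model, not instrument-level realism.

## Problem sizes

The test and acceptance runs use triplicate cultures throughout; 4-day,
12-hourly growth series; 5-day daily recovery series; 500-replicate
Monte-Carlo studies for estimator bias; and multi-experiment averages
(10–48 independently seeded triplicate experiments) for the stochastic
recovery checks, where a single triplicate constrains the one-or-two
informative daily intervals of a fast recovery ramp only loosely (the
per-triplicate RS spread at 3% noise, ~12%, matches the reported triplicate
scatter for the fast-recovering strain).

## Known limitations

- Connectivity ρ from a single 40-flashlet rise has ~±0.08 sampling spread
  at 3% noise — much looser than the amplitude-type parameters; it is
  reported with its fit SE and should be interpreted accordingly.
- The biexponential lifetime split (τ₁, τ₂, amplitudes) is ill-conditioned;
  the weighted τ is the stable summary.
- A truth with ρ at or near 0 is mean-biased upward by boundary truncation;
  that is a property of any bounded estimator, not removable by the bias
  correction.
- Preset trajectories are qualitative interpolations; only the anchored
  numbers above carry quantitative meaning.
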