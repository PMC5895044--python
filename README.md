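# frrphys

Variable chlorophyll fluorescence photophysiology for nitrogen-starvation
experiments: simulation and fitting of single-turnover FRRf (fast repetition
rate fluorometry) induction/relaxation transients, derivation of the PSII
parameter set and excitation-energy partition, pigment stoichiometry and
xanthophyll de-epoxidation metrics, and growth/recovery-competence scoring.

The package is aimed at phytoplankton physiologists who run batch
N-starvation and nitrate-resupply experiments on diatoms and prasinophytes
and want the full computational chain — from flashlet-level fluorescence
records to a cross-species recovery table — as tested, reusable code. A
built-in synthetic-data generator emulates triplicate cultures of four
species scenarios (the diatoms *Thalassiosira pseudonana* "Tp" and
*T. weissflogii* "Tw"; the prasinophytes *Ostreococcus tauri* "Ot" and
*Micromonas* sp. "Ms") through N-replete growth, progressive starvation and
recovery, with known ground truth, so every stage is testable without any
instrument data.

## The models

**FRRf induction (connected-units model).** A train of 40 sub-saturating
1.2 µs flashlets over 128 µs progressively closes PSII. With closed
fraction *C*, excitation rate *i* and effective absorption cross-section
σ<sub>PSII</sub> (Å² quanta⁻¹),

    dC/dt = i σ (1 − C)/(1 − ρC),
    F(C)  = Fo + (Fm − Fo) · C(1 − ρ)/(1 − ρC),

where ρ is the excitonic connectivity between reaction centers
(sigmoidicity of the rise). The closure ODE is solved in closed form via
the Lambert W function, so simulation and fitting use the exact
continuous-time model. Relaxation of fluorescence over 0.4 s tracks PSII
reopening as a biexponential with slow/fast lifetimes τ₁, τ₂; the
amplitude-weighted τ gives the reopening rate constant 1/τ.

**Derived parameters.** Fv/Fm = (Fm−Fo)/Fm; Fo′ = Fo′₁ₛ·Fm′/Fm′₁ₛ;
qP = (Fm′−Fs)/(Fm′−Fo′); ETR = σ′<sub>PSII</sub>·I·qP (e⁻ PSII⁻¹ s⁻¹);
PSII_active = Fo′₁ₛ/σ′₁ₛ; and the excitation-energy partition
Φ_PSII = (Fm′−Fs)/Fm′, Φ_NO = Fs/Fm, Φ_NPQ = 1 − (Φ_PSII + Φ_NO), which
sums to one by construction.

**Pigments.** De-epoxidation state DES = DT/(DD+DT) in diatoms and
(0.5·A + Z)/(V+A+Z) in prasinophytes; molar Antenna:Chl *a* ratios per
lineage; mass:mass Chl *a*:C and Chl *a*:N; and the spectrally averaged
Chl *a*-specific absorption ā* from 400–700 nm absorbance.

**Growth and recovery.** µ_max is the OLS slope of ln(cell density) vs
time; after nitrate resupply, daily recovery rates µ_R are regressed on
time and the recovery time T_R is where the regression reaches µ_max. The
recovery competence score RS = (1/T_R)/µ_max compares recovery across
species with different inherent growth rates.

## Worked example

```python
import frrphys as fp
from frrphys import synthetic, pipeline, photoparams

scn = synthetic.make_scenario("Ot", seed=1, noise_cv=0.03)
print(pipeline.growth_recovery_table(scn).round(3).to_string(index=False))

state = scn.phase("late_stationary")
fs = pipeline.derive_fluorescence_state(state, fp.FlashletProtocol(),
                                        noise_cv=0.03, seed=1)
d = photoparams.derive(fs, cell_density=state.cell_density)
print(f"Fv/Fm={d.fv_fm:.3f}  sigma'={d.sigma_prime:.0f}  qP={d.qp:.3f}")
print(f"Phi_PSII={d.phi_psii:.3f}  Phi_NPQ={d.phi_npq:.3f}  Phi_NO={d.phi_no:.3f}")
```

prints

```
species            stage  mu_max  mu_max_sd    RS  RS_sd  pct_change_RS
     Ot          replete   0.712      0.015   NaN    NaN        -77.243
     Ot early_stationary     NaN        NaN 0.761  0.199            NaN
     Ot   mid_stationary     NaN        NaN 0.558  0.189            NaN
     Ot  late_stationary     NaN        NaN 0.173  0.006            NaN

Fv/Fm=0.431  sigma'=545  qP=0.615
Phi_PSII=0.225  Phi_NPQ=0.386  Phi_NO=0.389
```

The recovery table shows *O. tauri*'s signature: robust recovery from early
stationary phase (RS ≈ 0.76) collapsing to RS ≈ 0.17 after prolonged
starvation, a ~77% loss of recovery competence. The fluorescence block
shows its late-stationary energy budget: a large induced energy-dependent
NPQ fraction (Φ_NPQ ≈ 0.39) at growth irradiance with depressed
photochemistry.

A `frrphys` command-line interface chains the same stages
(`simulate | fit | derive | pigments | growth | report | all`); every output
is plain CSV with a provenance header. Try
`frrphys report --seed 1 --outdir out/` for the four-species recovery
summary.

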