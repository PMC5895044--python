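"""Synthetic study-condition generator: four species scenarios with ground truth.

Generates every input the analysis pipeline consumes — FRRf transients over
actinic light steps, pigment/CN tables, growth and nitrate-resupply recovery
series, absorbance spectra — from species presets with known ground truth,
so each downstream stage can be validated without measured data.

The presets (``data/presets.yaml``) encode two kinds of numbers: quantities
anchored to reported values for these strains (growth rates, recovery
competence scores, replete Chl a:C and Antenna:Chl a, the per-cell Chl a
decline) and plausible-filler magnitudes (fluorescence yields,
cross-sections, lifetimes, NPQ amplitudes) that interpolate the qualitative
starvation-response patterns of each lineage.

Light response model.  Energy-dependent NPQ follows a Stern-Volmer
saturation NPQ(I) = npq_max * I/(I + I50); quenching scales Fo and Fm by
1/(1+NPQ), scales the effective cross-section by 1/(1 + 0.3*NPQ), and
partially relaxes during the 1 s dark gap (40% for energy-dependent
quenching, 5% for sustained quenching, which is "locked in").  The
steady-state closed fraction under actinic light balances the excitation
rate sigma' * I against the reopening rate 1/tau.  Because Fo and Fm are
quenched proportionally, the 1 s Fo' correction used by the pipeline is
exact on noiseless data, and every derived parameter can be computed
analytically from the ground truth for comparison.

Noise is multiplicative lognormal with unit mean (positivity-preserving, as
appropriate for fluorescence yields and per-cell quotas); replicate-level
variation is drawn once per replicate and multiplies the per-sample noise.
All randomness flows from explicit integer seeds through per-purpose
substreams, so every operation is reproducible record-for-record.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import yaml

from .frr_model import (
    FlashletProtocol,
    FluorescenceTrace,
    PSIIFitResult,
    closure_fraction,
    fluorescence_from_closure,
    simulate_transient,
)
from .growth import GrowthSeries
from .photoparams import QUANTA_PER_UMOL, M2_PER_A2, FluorescenceState
from .pigments import MOLAR_MASS, AbsorbanceSpectrum, PigmentProfile

__all__ = [
    "PhaseState",
    "SpeciesScenario",
    "LightStepTruth",
    "PRESET_NAMES",
    "load_presets",
    "make_scenario",
    "light_response",
    "true_fluorescence_state",
    "weighted_tau_us",
    "generate_transient",
    "generate_light_curve",
    "generate_pigment_profile",
    "generate_pigment_samples",
    "generate_absorbance",
    "generate_growth_series",
    "generate_recovery_series",
    "true_t_r",
]

PRESET_NAMES = ("Tp", "Tw", "Ot", "Ms")

#: umol photons m^-2 s^-1 -> quanta A^-2 s^-1
UMOL_TO_QUANTA_A2 = QUANTA_PER_UMOL * M2_PER_A2

#: fraction by which NPQ reduces the effective cross-section, per unit NPQ
K_SIGMA_NPQ = 0.3

#: fraction of NPQ that relaxes during the 1 s dark gap, per quenching mode
NPQ_RELAX = {"none": 0.0, "energy_dependent": 0.4, "sustained": 0.05}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PhaseState:
    """Ground-truth state of one culture at one growth phase."""

    phase: str
    fo: float
    fm: float
    sigma_psii: float                   # A^2 quanta^-1
    rho: float
    tau1: float                         # us, slow
    tau2: float                         # us, fast
    amp1: float
    amp2: float
    npq_mode: str
    npq_max: float
    npq_i50: float                      # umol photons m^-2 s^-1
    pigments_per_cell: dict             # pigment -> fg cell^-1
    c_per_cell: float                   # pg
    n_per_cell: float                   # pg
    cell_density: float                 # cells mL^-1
    abar_star: float                    # m^2 (mg Chl a)^-1
    lineage: str = "diatom"
    growth_irradiance: float = 85.0
    low_actinic_level: float = 21.0

    def __post_init__(self) -> None:
        if not self.fm > self.fo > 0:
            raise ValueError("require Fm > Fo > 0")
        if not 0 <= self.rho < 1:
            raise ValueError("require 0 <= rho < 1")
        if not self.tau1 > self.tau2 > 0:
            raise ValueError("require tau1 > tau2 > 0")
        if abs(self.amp1 + self.amp2 - 1) > 1e-9:
            raise ValueError("amplitudes must sum to 1")
        if self.npq_mode not in NPQ_RELAX:
            raise ValueError(f"unknown npq_mode {self.npq_mode!r}")
        if any(v < 0 for v in self.pigments_per_cell.values()):
            raise ValueError("pigment quotas must be >= 0")

    @property
    def chl_a_fg(self) -> float:
        return self.pigments_per_cell["chl_a"]

    def fit_truth(self) -> PSIIFitResult:
        """Dark-acclimated PSII parameters as a fit-result container."""
        return PSIIFitResult(fo=self.fo, fm=self.fm, sigma_psii=self.sigma_psii,
                             rho=self.rho, tau1=self.tau1, tau2=self.tau2,
                             amp1=self.amp1, amp2=self.amp2)


@dataclass
class SpeciesScenario:
    """One strain's trajectory through N starvation, plus recovery targets."""

    name: str
    full_name: str
    lineage: str
    mu_max: float                       # d^-1
    phases: list[PhaseState]
    recovery_rs: dict                   # stationary phase -> true RS
    growth_irradiance: float
    low_actinic_level: float
    replicates: int = 3
    noise_cv: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu_max <= 0:
            raise ValueError("mu_max must be positive")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")

    def phase(self, name: str) -> PhaseState:
        for st in self.phases:
            if st.phase == name:
                return st
        raise KeyError(f"scenario {self.name} has no phase {name!r}")

    @property
    def phase_names(self) -> list[str]:
        return [st.phase for st in self.phases]


@dataclass
class LightStepTruth:
    """Noise-free fluorescence observables at one actinic level."""

    irradiance: float
    fo_prime: float
    fm_prime: float
    sigma_prime: float
    fs: float
    c_ss: float
    fo_prime_1s: float
    fm_prime_1s: float
    sigma_prime_1s: float


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def load_presets() -> dict:
    from importlib.resources import files

    text = files("frrphys.data").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def make_scenario(preset_name: str, seed: int,
                  replicates: int = 3, noise_cv: float = 0.03) -> SpeciesScenario:
    """Build a fully populated species scenario from a named preset."""
    presets = load_presets()
    if preset_name not in presets:
        raise KeyError(
            f"unknown preset {preset_name!r}; available: {sorted(presets)}")
    cfg = presets[preset_name]
    phases = []
    for ph in cfg["phases"]:
        pigments = {"chl_a": float(ph["chl_a_fg"])}
        chl_mol = ph["chl_a_fg"] / MOLAR_MASS["chl_a"]
        for pig, ratio in ph["pigment_to_chl"].items():
            pigments[pig] = float(ratio) * chl_mol * MOLAR_MASS[pig]
        phases.append(PhaseState(
            phase=ph["phase"], fo=ph["fo"], fm=ph["fm"],
            sigma_psii=ph["sigma_psii"], rho=ph["rho"],
            tau1=ph["tau1"], tau2=ph["tau2"],
            amp1=ph["amp1"], amp2=1.0 - ph["amp1"],
            npq_mode=ph["npq_mode"], npq_max=ph["npq_max"],
            npq_i50=ph["npq_i50"],
            pigments_per_cell=pigments,
            c_per_cell=ph["c_pg"], n_per_cell=ph["n_pg"],
            cell_density=ph["cell_density"], abar_star=ph["abar_star"],
            lineage=cfg["lineage"],
            growth_irradiance=cfg["growth_irradiance"],
            low_actinic_level=cfg["low_actinic_level"],
        ))
    return SpeciesScenario(
        name=preset_name, full_name=cfg["full_name"], lineage=cfg["lineage"],
        mu_max=cfg["mu_max"], phases=phases,
        recovery_rs={k: float(v) for k, v in cfg["recovery_rs"].items()},
        growth_irradiance=cfg["growth_irradiance"],
        low_actinic_level=cfg["low_actinic_level"],
        replicates=replicates, noise_cv=noise_cv, seed=seed,
    )


# ---------------------------------------------------------------------------
# randomness
# ---------------------------------------------------------------------------

def _rng(seed: int, *labels) -> np.random.Generator:
    """Deterministic per-purpose substream derived from (seed, labels)."""
    tags = [zlib.crc32(str(lab).encode()) for lab in labels]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, *tags]))


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative lognormal noise with unit mean and given CV."""
    if cv <= 0:
        return 1.0 if size is None else np.ones(size)
    s2 = np.log1p(cv**2)
    return np.exp(rng.normal(-s2 / 2, np.sqrt(s2), size=size))


# ---------------------------------------------------------------------------
# fluorescence ground truth under actinic light
# ---------------------------------------------------------------------------

def weighted_tau_us(state: PhaseState) -> float:
    return state.amp1 * state.tau1 + state.amp2 * state.tau2


def light_response(state: PhaseState, irradiance: float) -> LightStepTruth:
    """Noise-free observables at one actinic irradiance (umol photons m-2 s-1)."""
    npq = 0.0
    if state.npq_mode != "none":
        npq = state.npq_max * irradiance / (irradiance + state.npq_i50)
    fo_p = state.fo / (1 + npq)
    fm_p = state.fm / (1 + npq)
    sigma_p = state.sigma_psii / (1 + K_SIGMA_NPQ * npq)

    k_close = sigma_p * irradiance * UMOL_TO_QUANTA_A2       # s^-1
    k_open = 1e6 / weighted_tau_us(state)                    # s^-1
    c_ss = k_close / (k_close + k_open)
    fs = fluorescence_from_closure(c_ss, fo_p, fm_p, state.rho)

    npq_1s = npq * (1 - NPQ_RELAX[state.npq_mode])
    return LightStepTruth(
        irradiance=irradiance,
        fo_prime=fo_p, fm_prime=fm_p, sigma_prime=sigma_p,
        fs=float(fs), c_ss=float(c_ss),
        fo_prime_1s=state.fo / (1 + npq_1s),
        fm_prime_1s=state.fm / (1 + npq_1s),
        sigma_prime_1s=state.sigma_psii / (1 + K_SIGMA_NPQ * npq_1s),
    )


def true_fluorescence_state(state: PhaseState) -> FluorescenceState:
    """Assemble the noiseless FluorescenceState the pipeline should recover."""
    low = light_response(state, state.low_actinic_level)
    growth = light_response(state, state.growth_irradiance)
    return FluorescenceState(
        fo=state.fo, fm=state.fm,
        fs=growth.fs, fm_prime=growth.fm_prime,
        fm_prime_1s=growth.fm_prime_1s, fo_prime_1s=growth.fo_prime_1s,
        sigma_prime=low.sigma_prime, sigma_prime_1s=growth.sigma_prime_1s,
        rho_prime=state.rho,
        growth_irradiance=state.growth_irradiance,
        tau_us=weighted_tau_us(state),
    )


# ---------------------------------------------------------------------------
# trace generation
# ---------------------------------------------------------------------------

def _apply_noise(trace: FluorescenceTrace, rng, cv: float) -> FluorescenceTrace:
    f = trace.fluorescence * _lognormal_factor(rng, cv, trace.fluorescence.size)
    return FluorescenceTrace(time_us=trace.time_us.copy(), fluorescence=f,
                             phase=trace.phase.copy(),
                             metadata=dict(trace.metadata),
                             warnings=list(trace.warnings))


def generate_transient(state: PhaseState, protocol: FlashletProtocol,
                       seed: int = 0, noise_cv: float = 0.0) -> FluorescenceTrace:
    """Dark-acclimated induction + relaxation transient with sampling noise.

    With ``noise_cv = 0`` the trace equals the forward-model simulation
    exactly; noise is multiplicative lognormal per flashlet record.
    """
    trace = simulate_transient(state.fit_truth(), protocol)
    trace.metadata.update(actinic=0.0, growth_phase=state.phase)
    return _apply_noise(trace, _rng(seed, "transient", state.phase), noise_cv)


def _induction_trace_from(f_base: float, f_max: float, sigma: float, rho: float,
                          protocol: FlashletProtocol, actinic: float,
                          kind: str) -> FluorescenceTrace:
    k = np.arange(1, protocol.n_induction_flashlets + 1)
    c = closure_fraction(k * protocol.flashlet_dose, sigma, rho)
    f = fluorescence_from_closure(c, f_base, f_max, rho)
    return FluorescenceTrace(
        time_us=protocol.induction_times,
        fluorescence=f,
        phase=np.full(k.size, "induction", dtype=object),
        metadata={"actinic": actinic, "kind": kind},
    )


def generate_light_curve(state: PhaseState, protocol: FlashletProtocol,
                         seed: int = 0, noise_cv: float = 0.0,
                         levels=None) -> list[dict]:
    """Traces for the full actinic-step sequence of one sample.

    Per level the instrument records an induction rise (from the
    steady-state yield Fs up to Fm' with the apparent cross-section at that
    light) and, after the 1 s dark gap, a second rise from Fo'_1s to Fm'_1s.
    The dark level additionally records the relaxation phase used for the
    reopening lifetimes.  Returns a list of dicts with keys ``level``,
    ``trace`` and (for actinic levels) ``post_gap_trace``.
    """
    if levels is None:
        levels = protocol.actinic_levels
    if levels[0] != 0:
        raise ValueError("first actinic level must be dark (0)")
    rng = _rng(seed, "light_curve", state.phase)
    steps = []
    for level in levels:
        if level == 0:
            trace = simulate_transient(state.fit_truth(), protocol)
            trace.metadata.update(actinic=0.0, kind="dark",
                                  growth_phase=state.phase)
            steps.append({"level": 0.0,
                          "trace": _apply_noise(trace, rng, noise_cv)})
            continue
        truth = light_response(state, level)
        rise = _induction_trace_from(truth.fs, truth.fm_prime,
                                     truth.sigma_prime, state.rho,
                                     protocol, level, "light_step")
        post = _induction_trace_from(truth.fo_prime_1s, truth.fm_prime_1s,
                                     truth.sigma_prime_1s, state.rho,
                                     protocol, level, "post_gap")
        steps.append({"level": float(level),
                      "trace": _apply_noise(rise, rng, noise_cv),
                      "post_gap_trace": _apply_noise(post, rng, noise_cv)})
    return steps


# ---------------------------------------------------------------------------
# pigments, CN, absorbance
# ---------------------------------------------------------------------------

def generate_pigment_profile(state: PhaseState, seed: int = 0,
                             noise_cv: float = 0.02, replicate: int = 0,
                             replicate_factor: float = 1.0,
                             label: str = "") -> PigmentProfile:
    """One HPLC + CHN sample: noisy per-cell pigment and C/N quotas."""
    rng = _rng(seed, "pigments", label, state.phase, replicate)
    conc = {p: v * replicate_factor * float(_lognormal_factor(rng, noise_cv))
            for p, v in state.pigments_per_cell.items()}
    return PigmentProfile(
        lineage=state.lineage,
        concentrations=conc,
        c_per_cell=state.c_per_cell * replicate_factor
        * float(_lognormal_factor(rng, noise_cv)),
        n_per_cell=state.n_per_cell * replicate_factor
        * float(_lognormal_factor(rng, noise_cv)),
        cell_density=state.cell_density * float(_lognormal_factor(rng, noise_cv)),
        sample_id=f"{state.phase}_rep{replicate}",
    )


def _replicate_factors(scenario: SpeciesScenario, purpose: str) -> np.ndarray:
    """One multiplicative offset per replicate culture, drawn once."""
    rng = _rng(scenario.seed, "replicate_effect", scenario.name, purpose)
    return _lognormal_factor(rng, scenario.noise_cv, scenario.replicates)


def generate_pigment_samples(scenario: SpeciesScenario, phases=None,
                             noise_cv: float | None = None) -> list[PigmentProfile]:
    """Triplicate pigment/CN samples for the requested phases."""
    if phases is None:
        phases = scenario.phase_names
    cv = scenario.noise_cv if noise_cv is None else noise_cv
    rep_fac = _replicate_factors(scenario, "pigments") if cv > 0 \
        else np.ones(scenario.replicates)
    out = []
    for name in phases:
        state = scenario.phase(name)
        for rep in range(scenario.replicates):
            prof = generate_pigment_profile(
                state, seed=scenario.seed, noise_cv=cv,
                replicate=rep, replicate_factor=float(rep_fac[rep]),
                label=scenario.name)
            prof.sample_id = f"{scenario.name}_{name}_rep{rep}"
            out.append(prof)
    return out


#: crude in-vivo Chl a-specific absorption shape: Soret and red Chl a bands
#: plus a carotenoid shoulder, on top of a small flat background
_ABS_BANDS = ((435.0, 25.0, 1.0), (490.0, 30.0, 0.55), (676.0, 12.0, 0.60))


def generate_absorbance(state: PhaseState, seed: int = 0,
                        noise_cv: float = 0.0,
                        pathlength_cm: float = 20.0,
                        step_nm: float = 1.0) -> AbsorbanceSpectrum:
    """Synthetic 400-700 nm absorbance spectrum whose spectrally averaged
    Chl a-specific absorption equals the phase's ground-truth value."""
    wl = np.arange(400.0, 700.0 + step_nm / 2, step_nm)
    shape = 0.05 + sum(a * np.exp(-0.5 * ((wl - mu) / sd) ** 2)
                       for mu, sd, a in _ABS_BANDS)
    a_star = shape * (state.abar_star / shape.mean())     # m^2 mg^-1
    # chl in the cuvette, mg m^-3 == ug L^-1
    chl = state.chl_a_fg * state.cell_density * 1e-6      # fg/cell * cells/mL
    absorbance = a_star * chl * (pathlength_cm * 1e-2) / np.log(10)
    rng = _rng(seed, "absorbance", state.phase)
    absorbance = absorbance * _lognormal_factor(rng, noise_cv, wl.size)
    return AbsorbanceSpectrum(wavelength_nm=wl, absorbance=absorbance,
                              pathlength_cm=pathlength_cm, chl_a_conc=chl)


# ---------------------------------------------------------------------------
# growth and recovery series
# ---------------------------------------------------------------------------

def generate_growth_series(scenario: SpeciesScenario, phase: str = "replete",
                           days: float = 4.0, interval: float = 0.5,
                           n0: float = 1e4,
                           noise_cv: float | None = None) -> list[GrowthSeries]:
    """Replicate ln-linear density series during balanced exponential growth."""
    scenario.phase(phase)       # raises for unknown phase
    cv = scenario.noise_cv if noise_cv is None else noise_cv
    t = np.arange(0.0, days + interval / 2, interval)
    out = []
    for rep in range(scenario.replicates):
        rng = _rng(scenario.seed, "growth", scenario.name, phase, rep)
        dens = n0 * np.exp(scenario.mu_max * t) * _lognormal_factor(rng, cv, t.size)
        out.append(GrowthSeries(timepoints=t, cell_density=dens,
                                replicate=rep, treatment="batch",
                                species=scenario.name, phase_of_origin=phase))
    return out


def true_t_r(scenario: SpeciesScenario, stationary_phase: str) -> float:
    """Ground-truth recovery time implied by the preset RS for that phase."""
    rs = scenario.recovery_rs[stationary_phase]
    return 1.0 / (rs * scenario.mu_max)


def _ln_density_ramp(t: np.ndarray, mu_max: float, t_r: float) -> np.ndarray:
    """Integral of the recovery ramp mu(t) = min(mu_max * t/T_R, mu_max)."""
    m = mu_max / t_r
    pre = m * np.minimum(t, t_r) ** 2 / 2
    post = mu_max * np.maximum(t - t_r, 0.0)
    return pre + post


def generate_recovery_series(scenario: SpeciesScenario, stationary_phase: str,
                             n_days: int = 5, n0: float = 1e4,
                             noise_cv: float | None = None,
                             include_control: bool = True) -> list[GrowthSeries]:
    """Daily-density recovery series after nitrate resupply, plus controls.

    The true recovery growth rate ramps linearly from zero at resupply to
    mu_max at the preset recovery time T_R = 1/(RS * mu_max) and stays at
    mu_max thereafter; densities follow the exact integral of that ramp.
    Control tubes (no N added) do not grow.
    """
    t_r = true_t_r(scenario, stationary_phase)
    cv = scenario.noise_cv if noise_cv is None else noise_cv
    t = np.arange(0.0, n_days + 0.5)
    out = []
    for rep in range(scenario.replicates):
        rng = _rng(scenario.seed, "recovery", scenario.name, stationary_phase, rep)
        dens = n0 * np.exp(_ln_density_ramp(t, scenario.mu_max, t_r)) \
            * _lognormal_factor(rng, cv, t.size)
        out.append(GrowthSeries(timepoints=t, cell_density=dens,
                                replicate=rep, treatment="recovery_N",
                                species=scenario.name,
                                phase_of_origin=stationary_phase))
        if include_control:
            ctrl = n0 * _lognormal_factor(rng, cv, t.size)
            out.append(GrowthSeries(timepoints=t, cell_density=ctrl,
                                    replicate=rep, treatment="recovery_control",
                                    species=scenario.name,
                                    phase_of_origin=stationary_phase))
    return out
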