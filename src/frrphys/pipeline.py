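"""End-to-end orchestration: traces -> fits -> derived parameter tables.

Chains the per-stage modules over a whole species scenario: fit the dark and
actinic-step transients of every replicate x phase, assemble
FluorescenceStates, derive the photophysiological parameter set, compute
pigment stoichiometry, and score growth/recovery — emitting tidy DataFrames
with one row per species x replicate x phase.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import frr_model, growth, photoparams, pigments, synthetic
from .frr_model import FlashletProtocol

__all__ = [
    "fit_light_steps",
    "assemble_state",
    "derive_fluorescence_state",
    "photophysiology_table",
    "pigment_table",
    "growth_recovery_table",
    "recovery_for_phase",
    "run_scenario",
]

#: actinic levels actually needed to assemble one FluorescenceState:
#: dark, the low-actinic reporting level, and the growth irradiance
def reporting_levels(state) -> tuple[float, ...]:
    return (0.0, state.low_actinic_level, state.growth_irradiance)


def fit_light_steps(steps: list[dict], protocol: FlashletProtocol) -> dict:
    """Fit every level of a light-step sequence.

    Returns ``{level: {"main": PSIIFitResult, "post_gap": PSIIFitResult}}``;
    the dark entry's ``main`` fit includes the relaxation lifetimes.
    """
    fits: dict = {}
    for step in steps:
        level = step["level"]
        entry = {"main": frr_model.fit_transient(step["trace"], protocol)}
        if "post_gap_trace" in step:
            entry["post_gap"] = frr_model.fit_induction(step["post_gap_trace"],
                                                        protocol)
        fits[level] = entry
    return fits


def assemble_state(fits: dict, low_actinic_level: float,
                   growth_irradiance: float) -> photoparams.FluorescenceState:
    """Build a FluorescenceState from per-level fits.

    Dark fit supplies Fo, Fm (and tau); the low-actinic fit supplies the
    reported sigma'/rho'; the growth-irradiance fit supplies Fs (the
    pre-flash steady state, i.e. the fitted baseline) and Fm', and its
    post-gap fit supplies Fo'_1s, Fm'_1s and sigma'_1s.
    """
    dark = fits[0.0]["main"]
    low = fits[low_actinic_level]["main"]
    g = fits[growth_irradiance]["main"]
    g1s = fits[growth_irradiance]["post_gap"]
    tau = frr_model.weighted_tau(dark) if np.isfinite(dark.tau1) else float("nan")
    stderr = {
        "fo": dark.stderr.get("fo"), "fm": dark.stderr.get("fm"),
        "sigma_prime": low.stderr.get("sigma_psii"),
        "rho_prime": low.stderr.get("rho"),
        "fs": g.stderr.get("fo"), "fm_prime": g.stderr.get("fm"),
        "fo_prime_1s": g1s.stderr.get("fo"),
        "fm_prime_1s": g1s.stderr.get("fm"),
        "sigma_prime_1s": g1s.stderr.get("sigma_psii"),
    }
    return photoparams.FluorescenceState(
        fo=dark.fo, fm=dark.fm,
        fs=g.fo, fm_prime=g.fm,
        fm_prime_1s=g1s.fm, fo_prime_1s=g1s.fo,
        sigma_prime=low.sigma_psii, sigma_prime_1s=g1s.sigma_psii,
        rho_prime=low.rho,
        growth_irradiance=growth_irradiance,
        tau_us=tau,
        stderr={k: v for k, v in stderr.items() if v is not None},
    )


def derive_fluorescence_state(state, protocol: FlashletProtocol,
                              noise_cv: float = 0.0,
                              seed: int = 0) -> photoparams.FluorescenceState:
    """Simulate + fit the light-step sequence of one ground-truth phase state."""
    steps = synthetic.generate_light_curve(state, protocol, seed=seed,
                                           noise_cv=noise_cv,
                                           levels=reporting_levels(state))
    fits = fit_light_steps(steps, protocol)
    return assemble_state(fits, state.low_actinic_level, state.growth_irradiance)


def photophysiology_table(scenario, protocol: FlashletProtocol | None = None,
                          phases=None) -> pd.DataFrame:
    """Fit and derive the full parameter set for every replicate x phase."""
    if protocol is None:
        protocol = FlashletProtocol()
    if phases is None:
        phases = scenario.phase_names
    rows = []
    for name in phases:
        st = scenario.phase(name)
        for rep in range(scenario.replicates):
            fstate = derive_fluorescence_state(
                st, protocol, noise_cv=scenario.noise_cv,
                seed=int(np.random.SeedSequence(
                    [scenario.seed % 2**31, rep]).generate_state(1)[0] % 2**31))
            derived = photoparams.derive(fstate, cell_density=st.cell_density)
            row = {"species": scenario.name, "phase": name, "replicate": rep,
                   "Fo": fstate.fo, "Fm": fstate.fm, "Fs": fstate.fs,
                   "Fm_prime": fstate.fm_prime,
                   "FvFm": derived.fv_fm, "sigma_prime": derived.sigma_prime,
                   "rho_prime": derived.rho_prime, "qp": derived.qp,
                   "ETR": derived.etr, "PSII_active": derived.psii_active,
                   "PSII_active_per_cell": derived.psii_active_per_cell,
                   "inv_tau": derived.inv_tau,
                   "phi_PSII": derived.phi_psii, "phi_NO": derived.phi_no,
                   "phi_NPQ": derived.phi_npq,
                   "flags": ";".join(derived.flags)}
            rows.append(row)
    return pd.DataFrame(rows)


def pigment_table(scenario, phases=None, noise_cv=None) -> pd.DataFrame:
    """Pigment stoichiometry rows for every replicate x phase."""
    profiles = synthetic.generate_pigment_samples(scenario, phases=phases,
                                                  noise_cv=noise_cv)
    q_n_max = scenario.phase("replete").n_per_cell
    rows = []
    for prof in profiles:
        ratios = pigments.normalized_ratios(prof, q_n_max=q_n_max)
        rows.append({
            "species": scenario.name,
            "sample": prof.sample_id,
            "lineage": prof.lineage,
            "chl_a": prof.get("chl_a"),
            "DES": pigments.des(prof),
            "antenna_to_chl_a": pigments.antenna_ratio(prof),
            "chl_a_to_c": ratios["chl_a_to_c"],
            "chl_a_to_n": ratios["chl_a_to_n"],
            "xanth_to_chl_a": ratios["xanth_to_chl_a"],
            "lutein_to_chl_a": ratios["lutein_to_chl_a"],
            "q_n_to_q_n_max": ratios["q_n_to_q_n_max"],
        })
    df = pd.DataFrame(rows)
    df["phase"] = df["sample"].str.extract(r"^[A-Za-z]+_(.+)_rep\d+$")
    return df


def recovery_for_phase(scenario, stationary_phase: str,
                       n_days: int = 5) -> growth.RecoveryResult:
    """Score recovery competence for one stationary phase of origin.

    RS is computed per replicate tube from its daily recovery growth rates
    and then averaged, matching how triplicate spread is reported.
    """
    series = synthetic.generate_recovery_series(scenario, stationary_phase,
                                                n_days=n_days)
    per_rep = []
    flags: list[str] = []
    t_rs = []
    for s in series:
        if s.treatment != "recovery_N":
            continue
        mid, mu_r, fl = growth.daily_mu_r(s)
        t_r, fl2 = growth.recovery_time(mid, mu_r, scenario.mu_max)
        per_rep.append(growth.rs_score(t_r, scenario.mu_max))
        t_rs.append(t_r)
        flags += fl + fl2
    per_rep = np.asarray(per_rep)
    return growth.RecoveryResult(
        mu_max=scenario.mu_max,
        t_r=float(np.mean(t_rs)),
        rs=float(np.mean(per_rep)),
        flags=sorted(set(flags)),
        per_replicate_rs=per_rep,
        rs_sd=float(np.std(per_rep, ddof=1)) if per_rep.size > 1 else float("nan"),
    )


def growth_recovery_table(scenario, n_days: int = 5) -> pd.DataFrame:
    """Table 3-shaped summary: mu_max and RS per stationary phase of origin."""
    mus = [growth.fit_mu(s)[0]
           for s in synthetic.generate_growth_series(scenario)]
    rows = [{"species": scenario.name, "stage": "replete",
             "mu_max": float(np.mean(mus)),
             "mu_max_sd": float(np.std(mus, ddof=1)),
             "RS": np.nan, "RS_sd": np.nan, "pct_change_RS": np.nan}]
    rs_by_phase = {}
    for phase in scenario.recovery_rs:
        res = recovery_for_phase(scenario, phase, n_days=n_days)
        rs_by_phase[phase] = res.rs
        rows.append({"species": scenario.name, "stage": phase,
                     "mu_max": np.nan, "mu_max_sd": np.nan,
                     "RS": res.rs, "RS_sd": res.rs_sd,
                     "pct_change_RS": np.nan})
    if {"early_stationary", "late_stationary"} <= rs_by_phase.keys():
        rows[0]["pct_change_RS"] = growth.pct_change_rs(
            rs_by_phase["early_stationary"], rs_by_phase["late_stationary"])
    return pd.DataFrame(rows)


def run_scenario(scenario, protocol: FlashletProtocol | None = None) -> dict:
    """Full pipeline over one scenario; returns the three output tables."""
    return {
        "photophysiology": photophysiology_table(scenario, protocol),
        "pigments": pigment_table(scenario),
        "growth_recovery": growth_recovery_table(scenario),
    }
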