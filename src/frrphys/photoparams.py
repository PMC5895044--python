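"""Derived photophysiological parameters from fitted fluorescence states.

Each operation implements one of the standard variable-fluorescence
derivations used in nutrient-stress photophysiology:

* Fv/Fm         = (Fm - Fo)/Fm, dark-acclimated maximum quantum yield
* Fo'           = Fo'_1s * Fm'/Fm'_1s, minimal fluorescence under actinic
                  light estimated from the 1 s dark-relaxed pair
* qP            = (Fm' - Fs)/(Fm' - Fo'), fraction of open PSII
* ETR           = sigma'_PSII * I * qP, electrons PSII^-1 s^-1
* PSII_active   = Fo'_1s / sigma'_1s, relative quantity of active PSII
* Phi_PSII      = (Fm' - Fs)/Fm'
* Phi_NO        = Fs/Fm          (dark-acclimated Fm in the denominator)
* Phi_NPQ       = 1 - Phi_PSII - Phi_NO

The three quantum yields partition the fate of excitation energy entering
PSII into photochemistry, regulated energy-dependent thermal dissipation
(NPQ) and constitutive energy-independent losses; they sum to one by
construction.  Out-of-range values are reported as computed and flagged, not
silently clipped, so pathological fits remain visible downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np

__all__ = [
    "FluorescenceState",
    "PhotoPhysiology",
    "fv_fm",
    "fo_prime",
    "qp",
    "etr",
    "psii_active",
    "yields",
    "propagate_se",
    "derive",
    "QUANTA_PER_UMOL",
    "M2_PER_A2",
]

#: Avogadro-derived photon count per umol photons
QUANTA_PER_UMOL = 6.022e17
#: m^2 per Angstrom^2
M2_PER_A2 = 1e-20


@dataclass
class FluorescenceState:
    """Fluorescence observables of one sample at one growth condition.

    Dark-acclimated Fo/Fm/sigma/rho, the steady-state and maximal yields at
    growth irradiance (Fs, Fm'), the 1 s dark-relaxed pair (Fo'_1s, Fm'_1s)
    with its cross-section sigma'_1s, and the low-actinic reporting values
    sigma', rho'.  ``stderr`` holds per-component fit standard errors keyed
    by field name.
    """

    fo: float
    fm: float
    fs: float
    fm_prime: float
    fm_prime_1s: float
    fo_prime_1s: float
    sigma_prime: float
    sigma_prime_1s: float
    rho_prime: float
    growth_irradiance: float = 85.0     # umol photons m^-2 s^-1
    tau_us: float = float("nan")        # amplitude-weighted reopening lifetime
    stderr: dict = field(default_factory=dict)

    def validate(self) -> list[str]:
        """Return a list of violated physical constraints (empty if clean)."""
        bad = []
        if not self.fm > self.fo > 0:
            bad.append("Fm <= Fo")
        if self.fm_prime > self.fm * (1 + 1e-6):
            bad.append("Fm' > Fm")
        if self.fs > self.fm_prime * (1 + 1e-6):
            bad.append("Fs > Fm'")
        if min(self.sigma_prime, self.sigma_prime_1s) <= 0:
            bad.append("sigma <= 0")
        return bad


@dataclass
class PhotoPhysiology:
    """The derived parameter set for one sample at growth irradiance."""

    fv_fm: float
    fo_prime: float
    qp: float
    etr: float                          # e- PSII^-1 s^-1
    psii_active: float                  # relative units (per volume)
    psii_active_per_cell: float         # after density normalisation
    inv_tau: float                      # s^-1
    phi_psii: float
    phi_no: float
    phi_npq: float
    sigma_prime: float
    rho_prime: float
    stderr: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)
             if f.name not in ("stderr", "flags")}
        d["flags"] = ";".join(self.flags)
        return d


# ---------------------------------------------------------------------------
# scalar derivations
# ---------------------------------------------------------------------------

def fv_fm(state: FluorescenceState) -> float:
    """Maximum potential quantum yield of PSII photochemistry, (Fm-Fo)/Fm."""
    if state.fm <= state.fo:
        raise ValueError("invalid state: Fm <= Fo")
    return (state.fm - state.fo) / state.fm


def fo_prime(state: FluorescenceState) -> tuple[float, list[str]]:
    """Estimated minimal fluorescence under actinic light.

    Fo' = Fo'_1s * {1 - [(Fm'_1s - Fm')/Fm'_1s]}, i.e. Fo'_1s scaled by the
    1 s relaxation of the maximal yield (algebraically Fo'_1s * Fm'/Fm'_1s).
    If Fm' exceeds Fm'_1s beyond tolerance the quenching did not relax during
    the gap; the value is still computed but flagged.
    """
    if state.fm_prime_1s <= 0:
        raise ValueError("Fm'_1s must be positive")
    flags = []
    if state.fm_prime > state.fm_prime_1s * (1 + 1e-6):
        flags.append("quenching_not_relaxed")
    return state.fo_prime_1s * (state.fm_prime / state.fm_prime_1s), flags


def qp(state: FluorescenceState, fo_p: float | None = None) -> tuple[float, list[str]]:
    """Photochemical quenching (Fm'-Fs)/(Fm'-Fo'), clipped to [0,1] with flag."""
    if fo_p is None:
        fo_p, _ = fo_prime(state)
    denom = state.fm_prime - fo_p
    if denom <= 0:
        raise ValueError("qP undefined: Fm' <= Fo'")
    value = (state.fm_prime - state.fs) / denom
    flags = []
    if not 0.0 <= value <= 1.0:
        flags.append("qp_clipped")
        value = min(max(value, 0.0), 1.0)
    return value, flags


def etr(state: FluorescenceState, qp_value: float) -> float:
    """Electron transfer rate from PSII at growth irradiance.

    ETR = sigma'_PSII [A^2 quanta^-1] x 1e-20 m^2/A^2
          x I [umol photons m^-2 s^-1] x 6.022e17 quanta umol^-1 x qP,
    in e- PSII^-1 s^-1.
    """
    return (state.sigma_prime * M2_PER_A2
            * state.growth_irradiance * QUANTA_PER_UMOL * qp_value)


def psii_active(state: FluorescenceState,
                cell_density: float | None = None) -> tuple[float, float]:
    """Quantity of active PSII reaction centers, Fo'_1s / sigma'_1s.

    Returns (per-volume relative value, per-cell value); the per-cell value
    is NaN when no cell density is supplied.
    """
    if state.sigma_prime_1s <= 0:
        raise ValueError("sigma'_1s must be positive")
    per_volume = state.fo_prime_1s / state.sigma_prime_1s
    per_cell = per_volume / cell_density if cell_density else float("nan")
    return per_volume, per_cell


def yields(state: FluorescenceState) -> tuple[float, float, float, list[str]]:
    """Excitation-energy partition (Phi_PSII, Phi_NO, Phi_NPQ).

    Phi_PSII = (Fm'-Fs)/Fm', Phi_NO = Fs/Fm with the dark-acclimated Fm as
    denominator, Phi_NPQ = 1 - (Phi_PSII + Phi_NO).  The triple sums to one
    by construction; components outside [0,1] are flagged, not clipped.
    """
    phi_psii = (state.fm_prime - state.fs) / state.fm_prime
    phi_no = state.fs / state.fm
    phi_npq = 1.0 - (phi_psii + phi_no)
    flags = [f"{name}_out_of_range"
             for name, v in (("phi_psii", phi_psii), ("phi_no", phi_no),
                             ("phi_npq", phi_npq))
             if not 0.0 <= v <= 1.0]
    return phi_psii, phi_no, phi_npq, flags


# ---------------------------------------------------------------------------
# error propagation
# ---------------------------------------------------------------------------

def propagate_se(func, values: dict, fit_ses: dict | None = None,
                 replicate_se: float = 0.0,
                 rel_step: float = 1e-6) -> tuple[float, list[str]]:
    """First-order (delta-method) standard error of ``func(**values)``.

    The gradient is taken by central finite differences; per-argument fit
    standard errors combine in quadrature, and the among-replicate SE is
    added in quadrature on top (curve-fit error and replicate scatter are
    independent sources).  If one source is missing the other is returned,
    flagged.
    """
    flags = []
    var = 0.0
    if fit_ses:
        for name, se in fit_ses.items():
            if name not in values or se is None or not np.isfinite(se):
                continue
            x = values[name]
            h = abs(x) * rel_step if x != 0 else rel_step
            hi = dict(values)
            lo = dict(values)
            hi[name] = x + h
            lo[name] = x - h
            grad = (func(**hi) - func(**lo)) / (2 * h)
            var += (grad * se) ** 2
    else:
        flags.append("no_fit_se")
    if replicate_se:
        var += replicate_se**2
    else:
        flags.append("no_replicate_se")
    return math.sqrt(var), flags


# ---------------------------------------------------------------------------
# full derivation
# ---------------------------------------------------------------------------

def derive(state: FluorescenceState,
           cell_density: float | None = None) -> PhotoPhysiology:
    """Compute the full derived parameter set for one fluorescence state."""
    flags = state.validate()
    fvfm = fv_fm(state)
    fo_p, fl = fo_prime(state)
    flags += fl
    qp_v, fl = qp(state, fo_p)
    flags += fl
    etr_v = etr(state, qp_v)
    psii_vol, psii_cell = psii_active(state, cell_density)
    phi_psii, phi_no, phi_npq, fl = yields(state)
    flags += fl
    inv_tau = 1e6 / state.tau_us if np.isfinite(state.tau_us) else float("nan")

    se = {}
    ses = state.stderr
    if ses:
        se["fv_fm"], _ = propagate_se(
            lambda fo, fm: (fm - fo) / fm,
            {"fo": state.fo, "fm": state.fm},
            {k: ses.get(k) for k in ("fo", "fm")})
        se["fo_prime"], _ = propagate_se(
            lambda fo_prime_1s, fm_prime, fm_prime_1s:
                fo_prime_1s * fm_prime / fm_prime_1s,
            {"fo_prime_1s": state.fo_prime_1s, "fm_prime": state.fm_prime,
             "fm_prime_1s": state.fm_prime_1s},
            {k: ses.get(k) for k in ("fo_prime_1s", "fm_prime", "fm_prime_1s")})

    return PhotoPhysiology(
        fv_fm=fvfm, fo_prime=fo_p, qp=qp_v, etr=etr_v,
        psii_active=psii_vol, psii_active_per_cell=psii_cell,
        inv_tau=inv_tau,
        phi_psii=phi_psii, phi_no=phi_no, phi_npq=phi_npq,
        sigma_prime=state.sigma_prime, rho_prime=state.rho_prime,
        stderr=se, flags=flags,
    )
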