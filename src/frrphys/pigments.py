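"""Pigment stoichiometry, xanthophyll de-epoxidation and Chl-specific absorption.

Lineage matters throughout: diatoms (Bacillariophyceae) run a
diadinoxanthin/diatoxanthin (DD/DT) xanthophyll cycle and use
fucoxanthin-chlorophyll proteins (fucoxanthin + Chl c1 + Chl c2) as light
harvesting antenna, whereas prasinophytes (Mamiellophyceae) run the
violaxanthin/antheraxanthin/zeaxanthin (V/A/Z) cycle and their Lhcp antenna
carries Chl b, MgDVP, prasinoxanthin and dihydrolutein.

De-epoxidation state:

    diatom        DES = DT / (DD + DT)
    prasinophyte  DES = (0.5 A + Z) / (V + A + Z)

Ratio conventions follow standard practice for these quantities: Chl a:C and
Chl a:N are mass:mass; pigment:pigment and pigment:Chl a ratios are molar,
using the shipped molar-mass table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MOLAR_MASS",
    "ANTENNA_PIGMENTS",
    "XANTHOPHYLL_PIGMENTS",
    "PIGMENT_NAMES",
    "PigmentProfile",
    "AbsorbanceSpectrum",
    "des",
    "antenna_ratio",
    "normalized_ratios",
    "percent_change",
    "a_bar_star",
]

#: literature molar masses, g mol^-1
MOLAR_MASS = {
    "chl_a": 893.5,
    "chl_b": 907.5,
    "chl_c1": 610.97,
    "chl_c2": 608.97,
    "fucoxanthin": 658.91,
    "mgdvp": 546.9,            # Mg-2,4-divinyl pheoporphyrin a5 monomethyl ester
    "prasinoxanthin": 600.87,
    "dihydrolutein": 570.9,
    "lutein": 568.87,
    "diadinoxanthin": 582.85,
    "diatoxanthin": 566.85,
    "violaxanthin": 600.85,
    "antheraxanthin": 584.85,
    "zeaxanthin": 568.87,
}

PIGMENT_NAMES = tuple(MOLAR_MASS)

#: light-harvesting-antenna-associated pigments per lineage
ANTENNA_PIGMENTS = {
    "diatom": ("fucoxanthin", "chl_c1", "chl_c2"),
    "prasinophyte": ("chl_b", "mgdvp", "prasinoxanthin", "dihydrolutein"),
}

#: xanthophyll-cycle pigment pools per lineage
XANTHOPHYLL_PIGMENTS = {
    "diatom": ("diadinoxanthin", "diatoxanthin"),
    "prasinophyte": ("violaxanthin", "antheraxanthin", "zeaxanthin"),
}


@dataclass
class PigmentProfile:
    """Per-sample pigment concentrations plus cellular C, N and density.

    ``concentrations`` is keyed by the canonical pigment names above; values
    share one unit (ug L^-1 or fg cell^-1 — every ratio here is unit-free as
    long as the basis is consistent).  C and N are pg cell^-1.
    """

    lineage: str
    concentrations: dict = field(default_factory=dict)
    c_per_cell: float = float("nan")     # pg cell^-1
    n_per_cell: float = float("nan")     # pg cell^-1
    cell_density: float = float("nan")   # cells mL^-1
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.lineage not in ANTENNA_PIGMENTS:
            raise ValueError(f"unknown lineage {self.lineage!r}")
        unknown = set(self.concentrations) - set(PIGMENT_NAMES)
        if unknown:
            raise ValueError(f"unknown pigments: {sorted(unknown)}")
        if any(v < 0 for v in self.concentrations.values()):
            raise ValueError("pigment concentrations must be >= 0")

    def get(self, pigment: str) -> float:
        return float(self.concentrations.get(pigment, 0.0))

    def moles(self, pigment: str) -> float:
        return self.get(pigment) / MOLAR_MASS[pigment]


@dataclass
class AbsorbanceSpectrum:
    """Blank-corrected absorbance over 400-700 nm on a regular grid."""

    wavelength_nm: np.ndarray
    absorbance: np.ndarray
    pathlength_cm: float                # integrating-cavity effective path
    chl_a_conc: float                   # ug L^-1 (== mg m^-3)

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise ValueError("wavelengths must be ascending")
        if self.pathlength_cm <= 0 or self.chl_a_conc <= 0:
            raise ValueError("pathlength and Chl a concentration must be > 0")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def des(profile: PigmentProfile) -> float:
    """Xanthophyll de-epoxidation state, lineage-dispatched, in [0, 1]."""
    if profile.lineage == "diatom":
        dd, dt = profile.get("diadinoxanthin"), profile.get("diatoxanthin")
        if dd + dt == 0:
            raise ValueError("DES undefined: DD + DT = 0")
        return dt / (dd + dt)
    v = profile.get("violaxanthin")
    a = profile.get("antheraxanthin")
    z = profile.get("zeaxanthin")
    if v + a + z == 0:
        raise ValueError("DES undefined: V + A + Z = 0")
    return (0.5 * a + z) / (v + a + z)


def antenna_ratio(profile: PigmentProfile) -> float:
    """Molar ratio of lineage antenna pigments to Chl a (antenna size proxy)."""
    chl_a_mol = profile.moles("chl_a")
    if chl_a_mol == 0:
        raise ValueError("Antenna:Chl a undefined: Chl a = 0")
    return sum(profile.moles(p) for p in ANTENNA_PIGMENTS[profile.lineage]) / chl_a_mol


def normalized_ratios(profile: PigmentProfile,
                      psii_active_per_cell: float | None = None,
                      q_n_max: float | None = None,
                      chl_a_per_cell: float | None = None) -> dict:
    """Normalised pigment/biomass ratios for one sample.

    Returns ``chl_a_to_c`` and ``chl_a_to_n`` (mass:mass, using per-cell Chl a
    when supplied, otherwise the profile concentration basis must already be
    per cell), molar ``xanth_to_chl_a`` and ``lutein_to_chl_a``,
    ``psii_active_to_chl_a`` when a PSII quota is given, and ``q_n_to_q_n_max``
    relative to the replete maximum N quota.  Ratios whose denominator is
    missing are reported as NaN and listed under ``"flags"``.
    """
    out: dict = {}
    flags = []
    chl_mass = chl_a_per_cell if chl_a_per_cell is not None else profile.get("chl_a")

    for key, denom_pg in (("chl_a_to_c", profile.c_per_cell),
                          ("chl_a_to_n", profile.n_per_cell)):
        if np.isfinite(denom_pg) and denom_pg > 0:
            out[key] = chl_mass / (denom_pg * 1e3)   # fg over pg -> mass:mass
        else:
            out[key] = float("nan")
            flags.append(key)

    chl_mol = profile.moles("chl_a")
    if chl_mol > 0:
        xanth = sum(profile.moles(p) for p in XANTHOPHYLL_PIGMENTS[profile.lineage])
        out["xanth_to_chl_a"] = xanth / chl_mol
        out["lutein_to_chl_a"] = profile.moles("lutein") / chl_mol
    else:
        out["xanth_to_chl_a"] = out["lutein_to_chl_a"] = float("nan")
        flags += ["xanth_to_chl_a", "lutein_to_chl_a"]

    if psii_active_per_cell is not None and chl_mass > 0:
        out["psii_active_to_chl_a"] = psii_active_per_cell / chl_mass
    if q_n_max is not None:
        if q_n_max > 0 and np.isfinite(profile.n_per_cell):
            out["q_n_to_q_n_max"] = profile.n_per_cell / q_n_max
        else:
            out["q_n_to_q_n_max"] = float("nan")
            flags.append("q_n_to_q_n_max")
    out["flags"] = flags
    return out


def percent_change(values_replete, values_stationary) -> float:
    """Percent change of the mean, 100 x (mean_late - mean_replete)/mean_replete."""
    m0 = float(np.mean(values_replete))
    m1 = float(np.mean(values_stationary))
    if m0 == 0:
        raise ValueError("percent change undefined: zero replete mean")
    return 100.0 * (m1 - m0) / m0


def a_bar_star(spectrum: AbsorbanceSpectrum,
               weights: np.ndarray | None = None,
               negative_tol: float = 1e-3) -> float:
    """Spectrally averaged Chl a-specific absorption coefficient, m^2 (mg Chl a)^-1.

    a(lambda) = ln(10) * absorbance / pathlength (m^-1), a* = a/[Chl a], and
    the average over 400-700 nm is unweighted by default; passing ``weights``
    (e.g. a growth-lamp emission spectrum on the same grid) switches to a
    weighted spectral mean.  Raises if the blank-corrected absorbance dips
    below ``-negative_tol``.
    """
    if np.any(spectrum.absorbance < -negative_tol):
        raise ValueError("negative corrected absorbance beyond tolerance")
    a = np.log(10) * spectrum.absorbance / (spectrum.pathlength_cm * 1e-2)
    a_star = a / spectrum.chl_a_conc
    if weights is None:
        return float(np.mean(a_star))
    w = np.asarray(weights, dtype=float)
    if w.shape != a_star.shape:
        raise ValueError("weights must match the wavelength grid")
    return float(np.sum(w * a_star) / np.sum(w))
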