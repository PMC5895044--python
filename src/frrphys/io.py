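"""CSV dialects and provenance-stamped table I/O.

All on-disk artifacts are plain CSV with a header row.  Files written by the
package carry provenance metadata (package version, seed, config hash) as
leading ``#`` comment lines, which the readers skip.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .frr_model import FluorescenceTrace
from .growth import GrowthSeries
from .pigments import PIGMENT_NAMES, AbsorbanceSpectrum, PigmentProfile

__all__ = [
    "config_hash",
    "write_table",
    "read_table",
    "trace_to_frame",
    "trace_from_frame",
    "profiles_to_frame",
    "profiles_from_frame",
    "growth_to_frame",
    "growth_from_frame",
    "spectrum_to_frame",
    "spectrum_from_frame",
]

TRACE_COLUMNS = ["time_us", "phase", "actinic_umol_m2_s", "fluorescence",
                 "replicate", "growth_phase"]
GROWTH_COLUMNS = ["day", "cells_per_ml", "replicate", "treatment", "species",
                  "phase_of_origin"]


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, seed=None, config: dict | None = None) -> None:
    """Write a CSV with a provenance comment header."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# frrphys {__version__}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if config is not None:
        lines.append(f"# config_hash={config_hash(config)}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table` (comment lines skipped)."""
    try:
        return pd.read_csv(path, comment="#")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed CSV {path}: {exc}") from exc


def _require(df: pd.DataFrame, columns, what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing required columns: {missing}")


# -- fluorescence traces ----------------------------------------------------

def trace_to_frame(trace: FluorescenceTrace, replicate: int = 0) -> pd.DataFrame:
    meta = trace.metadata
    return pd.DataFrame({
        "time_us": trace.time_us,
        "phase": trace.phase,
        "actinic_umol_m2_s": meta.get("actinic", 0.0),
        "fluorescence": trace.fluorescence,
        "replicate": replicate,
        "growth_phase": meta.get("growth_phase", ""),
    })


def trace_from_frame(df: pd.DataFrame) -> FluorescenceTrace:
    _require(df, TRACE_COLUMNS[:4], "trace CSV")
    return FluorescenceTrace(
        time_us=df["time_us"].to_numpy(float),
        fluorescence=df["fluorescence"].to_numpy(float),
        phase=df["phase"].to_numpy(object),
        metadata={"actinic": float(df["actinic_umol_m2_s"].iloc[0]),
                  "growth_phase": str(df.get("growth_phase", pd.Series([""])).iloc[0])},
    )


# -- pigment profiles -------------------------------------------------------

def profiles_to_frame(profiles: list[PigmentProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {"sample": p.sample_id, "lineage": p.lineage,
               "c_per_cell_pg": p.c_per_cell, "n_per_cell_pg": p.n_per_cell,
               "cells_per_ml": p.cell_density}
        row.update({name: p.get(name) for name in PIGMENT_NAMES})
        rows.append(row)
    return pd.DataFrame(rows)


def profiles_from_frame(df: pd.DataFrame) -> list[PigmentProfile]:
    _require(df, ["sample", "lineage", "chl_a"], "pigment CSV")
    out = []
    for _, row in df.iterrows():
        conc = {name: float(row[name]) for name in PIGMENT_NAMES
                if name in row and pd.notna(row[name])}
        out.append(PigmentProfile(
            lineage=row["lineage"], concentrations=conc,
            c_per_cell=float(row.get("c_per_cell_pg", np.nan)),
            n_per_cell=float(row.get("n_per_cell_pg", np.nan)),
            cell_density=float(row.get("cells_per_ml", np.nan)),
            sample_id=str(row["sample"])))
    return out


# -- growth series ----------------------------------------------------------

def growth_to_frame(series_list: list[GrowthSeries]) -> pd.DataFrame:
    frames = []
    for s in series_list:
        frames.append(pd.DataFrame({
            "day": s.timepoints, "cells_per_ml": s.cell_density,
            "replicate": s.replicate, "treatment": s.treatment,
            "species": s.species, "phase_of_origin": s.phase_of_origin}))
    return pd.concat(frames, ignore_index=True)


def growth_from_frame(df: pd.DataFrame) -> list[GrowthSeries]:
    _require(df, GROWTH_COLUMNS[:4], "growth CSV")
    out = []
    keys = ["species", "phase_of_origin", "treatment", "replicate"]
    for (sp, ph, tr, rep), grp in df.groupby(keys, sort=False):
        grp = grp.sort_values("day")
        out.append(GrowthSeries(
            timepoints=grp["day"].to_numpy(float),
            cell_density=grp["cells_per_ml"].to_numpy(float),
            replicate=int(rep), treatment=str(tr), species=str(sp),
            phase_of_origin=str(ph)))
    return out


# -- absorbance spectra -----------------------------------------------------

def spectrum_to_frame(spec: AbsorbanceSpectrum) -> pd.DataFrame:
    df = pd.DataFrame({"wavelength_nm": spec.wavelength_nm,
                       "absorbance": spec.absorbance})
    df["pathlength_cm"] = spec.pathlength_cm
    df["chl_a_ug_l"] = spec.chl_a_conc
    return df


def spectrum_from_frame(df: pd.DataFrame) -> AbsorbanceSpectrum:
    _require(df, ["wavelength_nm", "absorbance"], "absorbance CSV")
    return AbsorbanceSpectrum(
        wavelength_nm=df["wavelength_nm"].to_numpy(float),
        absorbance=df["absorbance"].to_numpy(float),
        pathlength_cm=float(df["pathlength_cm"].iloc[0]),
        chl_a_conc=float(df["chl_a_ug_l"].iloc[0]))
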