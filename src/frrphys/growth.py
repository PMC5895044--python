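"""Growth rates, recovery time after nitrate resupply, and recovery scoring.

The maximum growth rate mu_max (d^-1) is the ordinary least-squares slope of
ln(cell density) versus time during N-replete balanced exponential growth.
After nitrate is resupplied to an N-starved culture, daily recovery growth
rates mu_R(d) = ln(N_d/N_{d-1})/dt ramp back up; the recovery time T_R is
the time at which a linear regression of mu_R on time reaches mu_max, and
the dimensionless recovery competence score

    RS = (1/T_R) / mu_max

normalises the inverse recovery time by a species' inherent growth rate so
that recovery competence can be compared across taxa with very different
metabolic rates.

Because daily mu_R values are interval averages, each value is placed at the
midpoint of its sampling interval for the regression, and an exact (0, 0)
anchor is included by default: an N-starved culture has zero growth at the
moment of resupply (its unamended control never grows).  Intervals at or
near the mu_max plateau are excluded, as is the partially-plateaued crossing
interval, so that on clean ramp data the regression recovers the true
crossing time exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "GrowthSeries",
    "RecoveryResult",
    "fit_mu",
    "daily_mu_r",
    "recovery_time",
    "rs_score",
    "pct_change_rs",
]


@dataclass
class GrowthSeries:
    """Cell-density time series for one culture tube."""

    timepoints: np.ndarray              # days
    cell_density: np.ndarray            # cells mL^-1
    replicate: int = 0
    treatment: str = "batch"            # batch | recovery_N | recovery_control
    species: str = ""
    phase_of_origin: str = ""

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.cell_density = np.asarray(self.cell_density, dtype=float)
        if self.timepoints.size < 3:
            raise ValueError("need >= 3 timepoints")
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("times must be ascending")
        if np.any(self.cell_density <= 0):
            raise ValueError("densities must be positive")
        if self.treatment not in ("batch", "recovery_N", "recovery_control"):
            raise ValueError(f"unknown treatment {self.treatment!r}")


@dataclass
class RecoveryResult:
    """Recovery metrics for one species x stationary phase."""

    mu_max: float                       # d^-1
    t_r: float                          # days (inf when recovery failed)
    rs: float
    flags: list[str] = field(default_factory=list)
    per_replicate_rs: np.ndarray | None = None
    rs_sd: float = float("nan")


def fit_mu(series: GrowthSeries) -> tuple[float, float]:
    """OLS slope of ln(density) vs time: the growth rate mu (d^-1) and its SE."""
    res = stats.linregress(series.timepoints, np.log(series.cell_density))
    return float(res.slope), float(res.stderr)


def daily_mu_r(series: GrowthSeries) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-interval recovery growth rates mu_R = ln(N_d/N_{d-1})/dt.

    Returns (interval midpoints in days, mu_R values, flags).  Sampling gaps
    longer than 1.5x the median interval are flagged but the interval-average
    rate over the gap is still reported.
    """
    t = series.timepoints
    dt = np.diff(t)
    mu = np.diff(np.log(series.cell_density)) / dt
    mid = t[:-1] + dt / 2
    flags = []
    if np.any(dt > 1.5 * dt.min()):
        flags.append("sampling_gap")
    return mid, mu, flags


def recovery_time(mu_r_times: np.ndarray,
                  mu_r: np.ndarray,
                  mu_max: float,
                  plateau_tol: float = 0.1,
                  include_origin: bool = True) -> tuple[float, list[str]]:
    """Time for the mu_R-vs-time regression line to reach mu_max.

    ``plateau_tol`` defines the plateau as values within that fraction of
    mu_max; plateau intervals are excluded from the regression, and so is the
    last pre-plateau interval when at least two remain, because the interval
    containing the crossing averages ramp and plateau growth and would bias
    the slope.  Extrapolation beyond the last observation is allowed (the
    failed-recovery case needs it) and flagged ``extrapolated``.  A
    non-positive slope with mu_R below mu_max throughout means no recovery:
    T_R is infinite (RS = 0), flagged ``no_recovery``.
    """
    mu_r_times = np.asarray(mu_r_times, dtype=float)
    mu_r = np.asarray(mu_r, dtype=float)
    if mu_r.size < 1 or mu_max <= 0:
        raise ValueError("need mu_R observations and mu_max > 0")

    flags: list[str] = []
    if mu_r[0] >= mu_max:
        # already at full speed within the first interval: lower bound only
        t_first = 2 * mu_r_times[0]      # interval end from its midpoint
        return t_first, ["t_r_lower_bound"]

    # failed recovery: the observed rates alone (no origin anchor) trend flat
    # or downward while never reaching mu_max
    if np.all(mu_r < mu_max) and mu_r.size >= 2 \
            and np.polyfit(mu_r_times, mu_r, 1)[0] <= 0:
        return float("inf"), ["no_recovery"]

    at_plateau = mu_r >= (1.0 - plateau_tol) * mu_max
    first_plateau = int(np.argmax(at_plateau)) if at_plateau.any() else mu_r.size
    use = np.arange(first_plateau)
    if at_plateau.any() and use.size >= 2:
        use = use[:-1]                  # drop the partially-plateaued crossing interval
    if use.size == 0:
        raise ValueError("no pre-plateau mu_R points to regress")

    x = mu_r_times[use]
    y = mu_r[use]
    if include_origin:
        x = np.concatenate([[0.0], x])
        y = np.concatenate([[0.0], y])
    if x.size < 2:
        raise ValueError("need >= 2 points (including origin) for the regression")
    slope, intercept = np.polyfit(x, y, 1)

    if slope <= 0:
        if np.all(mu_r < mu_max):
            return float("inf"), ["no_recovery"]
        raise ValueError("non-positive slope with mu_R crossing mu_max: ambiguous")
    t_r = (mu_max - intercept) / slope
    if t_r > mu_r_times[-1] + (mu_r_times[-1] - mu_r_times[0]) / max(mu_r.size - 1, 1) / 2:
        flags.append("extrapolated")
    return float(t_r), flags


def rs_score(t_r: float, mu_max: float) -> float:
    """Recovery competence score RS = (1/T_R)/mu_max; 0 for failed recovery."""
    if mu_max <= 0:
        raise ValueError("mu_max must be positive")
    if not t_r > 0:
        raise ValueError("T_R must be positive")
    if np.isinf(t_r):
        return 0.0
    return (1.0 / t_r) / mu_max


def pct_change_rs(rs_early: float, rs_late: float) -> float:
    """Percent change in RS across progressive starvation, 100 (late-early)/early."""
    if rs_early == 0:
        raise ValueError("percent change undefined: RS_early = 0")
    return 100.0 * (rs_late - rs_early) / rs_early
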