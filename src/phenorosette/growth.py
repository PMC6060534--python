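"""Per-individual sigmoid growth modeling.

Rosette mass over time is modeled with the three-parameter logistic

    M(t) = A / (1 + exp((t_inf - t) / B))

where A is the upper asymptote (fixed to the dry mass measured at
maturity, the central identifiability choice: only B and t_inf are
estimated), t_inf the inflection time at which M = A/2 and absolute growth
is maximal, and B the inverse of the exponential growth coefficient
r = 1/B (per day).  Derived dynamics:

    GR(t)  = r * M(t) * (1 - M(t)/A)      absolute growth rate, mass/day
    RGR(t) = GR(t)/M(t) = r * (1 - M(t)/A)  relative growth rate, 1/day

RGR here is in day^-1 (mass per unit mass per day); multiply by
``RGR_PER_GRAM`` (1000) to report mg g^-1 day^-1.  The growth start t0 of
each plant is the first day its size reaches the size of the biggest plant
measured on the common first day (which normalizes trajectories across
germination speeds); duration = maturity_day - t0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

__all__ = [
    "MassSeries",
    "GrowthFit",
    "GrowthTraits",
    "RGR_PER_GRAM",
    "determine_t0",
    "fit_logistic",
    "logistic_mass",
    "growth_rate",
    "rgr",
    "traits_at_inflection",
]

RGR_PER_GRAM = 1000.0  # day^-1  ->  mg g^-1 day^-1


@dataclass
class MassSeries:
    """One plant's estimated-mass time series plus its final mass."""

    plant_id: str
    times: np.ndarray  # days, strictly increasing
    masses: np.ndarray  # mg
    A_final: float  # mg, measured at maturity
    maturity_day: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.times.size < 3:
            raise ValueError("need at least 3 observations")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not self.A_final > 0:
            raise ValueError("A_final must be > 0")


@dataclass
class GrowthFit:
    """Fitted logistic parameters and diagnostics for one plant."""

    plant_id: str
    A: float
    B: float
    t_inf: float
    r: float  # = 1/B exactly
    t0: float
    duration: float
    rss: float
    converged: bool


@dataclass
class GrowthTraits:
    """Closed-form traits at the inflection point."""

    M_at_tinf: float  # = A/2
    GR_at_tinf: float  # = r*A/4
    RGR_at_tinf: float  # = r/2, in day^-1


def determine_t0(
    sizes: pd.DataFrame,
    plant_col: str = "plant_id",
    day_col: str = "day",
    size_col: str = "size",
) -> tuple[dict[str, float], float, list[str]]:
    """Per-plant growth start from a long table of (plant, day, size).

    The threshold is the size of the biggest measured plant on the common
    first day; each plant's t0 is the earliest day its size reaches that
    threshold.  Returns (t0 per plant, threshold, excluded plant ids);
    plants never reaching the threshold are excluded with a warning.
    Re-express each retained series as days after its own t0 before
    fitting.
    """
    df = sizes[[plant_col, day_col, size_col]].dropna()
    first_day = df[day_col].min()
    at_first = df[df[day_col] == first_day]
    if at_first.empty:
        raise ValueError("no observations on the first day")
    threshold = float(at_first[size_col].max())
    t0s: dict[str, float] = {}
    excluded: list[str] = []
    for pid, g in df.groupby(plant_col, sort=False):
        g = g.sort_values(day_col)
        hit = g[g[size_col] >= threshold]
        if hit.empty:
            excluded.append(pid)
            logger.warning("plant %s never reaches size threshold; excluded", pid)
        else:
            t0s[pid] = float(hit[day_col].iloc[0])
    return t0s, threshold, excluded


def _logistic(t: np.ndarray, A: float, B: float, t_inf: float) -> np.ndarray:
    return A / (1.0 + np.exp((t_inf - t) / B))


def _initial_guess(series: MassSeries) -> tuple[float, float]:
    t, m, A = series.times, series.masses, series.A_final
    half = A / 2.0
    above = np.flatnonzero(m >= half)
    if above.size == 0:
        t_inf0 = t[-1]
    elif above[0] == 0:
        t_inf0 = t[0]
    else:
        i = above[0]
        # linear interpolation of the first upward crossing of A/2
        t_inf0 = t[i - 1] + (half - m[i - 1]) / (m[i] - m[i - 1]) * (
            t[i] - t[i - 1]
        )
    frac = np.clip(m / A, 1e-6, 1 - 1e-6)
    logit = np.log(frac / (1 - frac))
    slope = np.polyfit(t, logit, 1)[0]
    B0 = 1.0 / slope if slope > 1e-8 else (t[-1] - t[0]) / 4.0
    return max(B0, 1e-3), float(t_inf0)


def fit_logistic(
    series: MassSeries, t0: float = 0.0, max_iter: int = 500
) -> GrowthFit:
    """Fit (B, t_inf) by nonlinear least squares with A fixed to the
    measured final mass.

    Initialization: t_inf from the interpolated first crossing of A/2, B
    from the slope of logit(M/A) against t.  Converges when the relative
    change in the residual sum of squares falls below 1e-10 (or after
    ``max_iter`` evaluations; then the best iterate is returned with
    ``converged=False``).
    """
    A = series.A_final
    t, m = series.times, series.masses

    def resid(p: np.ndarray) -> np.ndarray:
        return _logistic(t, A, p[0], p[1]) - m

    B0, t_inf0 = _initial_guess(series)
    sol = least_squares(
        resid,
        x0=[B0, t_inf0],
        bounds=([1e-9, -np.inf], [np.inf, np.inf]),
        ftol=1e-10,
        xtol=1e-12,
        gtol=1e-12,
        max_nfev=max_iter,
    )
    B, t_inf = float(sol.x[0]), float(sol.x[1])
    rss = float(2.0 * sol.cost)
    converged = bool(sol.status > 0)
    if not converged:
        logger.warning(
            "logistic fit for %s did not converge; best iterate returned",
            series.plant_id,
        )
    return GrowthFit(
        plant_id=series.plant_id,
        A=A,
        B=B,
        t_inf=t_inf,
        r=1.0 / B,
        t0=t0,
        duration=series.maturity_day - t0,
        rss=rss,
        converged=converged,
    )


def logistic_mass(fit: GrowthFit, t) -> np.ndarray:
    """M(t) for a fitted curve."""
    return _logistic(np.asarray(t, dtype=float), fit.A, fit.B, fit.t_inf)


def growth_rate(fit: GrowthFit, t) -> np.ndarray:
    """Absolute growth rate GR(t) = r * M(t) * (1 - M(t)/A), mass/day."""
    m = logistic_mass(fit, t)
    return fit.r * m * (1.0 - m / fit.A)


def rgr(fit: GrowthFit, t) -> np.ndarray:
    """Relative growth rate RGR(t) = r * (1 - M(t)/A), in day^-1.

    Multiply by RGR_PER_GRAM to report in mg g^-1 day^-1.
    """
    m = logistic_mass(fit, t)
    return fit.r * (1.0 - m / fit.A)


def traits_at_inflection(fit: GrowthFit) -> GrowthTraits:
    """Traits where GR is maximal: M = A/2, GR = r*A/4, RGR = r/2."""
    return GrowthTraits(
        M_at_tinf=fit.A / 2.0,
        GR_at_tinf=fit.r * fit.A / 4.0,
        RGR_at_tinf=fit.r / 2.0,
    )
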