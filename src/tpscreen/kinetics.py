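"""Photocatalytic degradation kinetics and TP appearance/disappearance profiles.

Parent disappearance under TiO2 photocatalysis is modelled as pseudo-first
order, C(t) = C0 * exp(-k t) - the standard description when the surface
reaction is far from saturation.  The fit is nonlinear least squares on the
exponential itself (not a log-linear transform), so zero-valued tails are
handled gracefully.  TP abundances are profiled over the sampled time grid
{0, 5, 10, 15, 30, 60, 120} min; the only summary extracted from them is the
time of maximum signal, with ties broken toward the earlier time point.

Drug presets pin the rate constants to the observed end points: haloperidol
93.2% removal at 120 min (k ~ 0.0224 1/min) and aripiprazole 10% remaining
at 5 min (k ~ 0.4605 1/min).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "TIME_GRID_MIN",
    "KINETIC_PRESETS",
    "ConcentrationTimeSeries",
    "DecayFit",
    "TPProfile",
    "fit_first_order",
    "percent_removal",
    "profile_tmax",
]

#: Photocatalysis sampling grid (minutes).
TIME_GRID_MIN: tuple[float, ...] = (0.0, 5.0, 10.0, 15.0, 30.0, 60.0, 120.0)

#: First-order rate constants (1/min) anchored to the reported end points.
KINETIC_PRESETS: dict[str, float] = {
    "haloperidol": -math.log(1 - 0.932) / 120.0,
    "aripiprazole": -math.log(0.10) / 5.0,
}


@dataclass
class ConcentrationTimeSeries:
    """Concentration or normalized signal (C/C0) versus time."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("concentrations must be non-negative")


@dataclass
class DecayFit:
    """Fitted pseudo-first-order decay."""

    k: float  # 1/min
    c0: float
    r_squared: float

    @property
    def half_life_min(self) -> float:
        return math.inf if self.k == 0 else math.log(2) / self.k


@dataclass
class TPProfile:
    """Per-TP-isomer EIC apex intensity versus photocatalysis time."""

    name: str
    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must have equal length")


def fit_first_order(series: ConcentrationTimeSeries) -> DecayFit:
    """Nonlinear least-squares fit of C0 * exp(-k t).

    Requires at least three points and a positive value at the first time.
    A constant series returns k = 0 with a warning.  The starting point for
    the optimizer comes from a log-linear regression over the positive
    values.
    """
    t, y = series.times, series.values
    if t.size < 3:
        raise ValueError("need at least 3 time points")
    if y[0] <= 0:
        raise ValueError("initial value must be positive")
    if np.allclose(y, y[0]):
        warnings.warn("constant series; returning k = 0", stacklevel=2)
        return DecayFit(k=0.0, c0=float(y[0]), r_squared=1.0)
    pos = y > 0
    slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
    k0 = max(-slope, 1e-6)
    popt, _ = curve_fit(
        lambda tt, c0, k: c0 * np.exp(-k * tt),
        t,
        y,
        p0=(math.exp(intercept), k0),
        bounds=((0.0, 0.0), (np.inf, np.inf)),
        maxfev=10000,
    )
    c0, k = float(popt[0]), float(popt[1])
    resid = y - c0 * np.exp(-k * t)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DecayFit(k=k, c0=c0, r_squared=r2)


def percent_removal(fit: DecayFit, t_min: float) -> float:
    """Removal percentage 100 * (1 - exp(-k t)) at time ``t_min``."""
    if t_min < 0:
        raise ValueError("time must be non-negative")
    return 100.0 * (1.0 - math.exp(-fit.k * t_min))


def profile_tmax(profile: TPProfile) -> float:
    """Time of maximum signal over the sampled grid (earlier time on ties)."""
    if profile.times.size < 2:
        raise ValueError("need at least 2 time points")
    return float(profile.times[int(np.argmax(profile.intensities))])
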