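"""Rate of D2 occupancy change (RODOC): swings, discontinuation drops, limits.

Two quantities proxy withdrawal burden:

* the absolute occupancy swing between steady-state peak and trough inside
  one inter-dose interval, and
* after abrupt discontinuation, the largest occupancy decline over any
  30-day sliding window of the residual tail.

Both are compared against taper-rate classes of 1.25 (very slow), 2.5
(slow), 5 (moderate) and 10 (fast) percentage points. For a residual tail
decaying purely at the terminal rate ke with occupancy passing through the
mid range, the peak 30-day drop has the closed form
``Emax * tanh(15 * ke / 2)`` (the occupancy trajectory is logistic in time),
which serves as an analytic cross-check on the simulated value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .occupancy import occupancy_from_concentration, occupancy_profile
from .params import DrugParams
from .pk import DEFAULT_PROFILE_MODEL, ProfileModel, SteadyStateSummary, day_grid, steady_state_tail
from .profiles import OccupancyProfile

__all__ = [
    "RateClass",
    "RATE_CLASSES",
    "interdose_swing",
    "swing_from_concentrations",
    "abrupt_discontinuation_profile",
    "peak_window_drop",
    "peak_drop_terminal_limit",
    "classify_rate",
]

#: minimum horizon (days) for a discontinuation run; the steep mid-occupancy
#: region falls months after the final dose and must be covered
MIN_HORIZON_DAYS = 300.0


@dataclass(frozen=True)
class RateClass:
    """A taper-speed constraint: maximum occupancy change per inter-dose
    interval (or per 30 days for abrupt cessation)."""

    name: str
    limit_points: float


RATE_CLASSES: tuple[RateClass, ...] = (
    RateClass("very_slow", 1.25),
    RateClass("slow", 2.5),
    RateClass("moderate", 5.0),
    RateClass("fast", 10.0),
)


def rate_class(name: str) -> RateClass:
    for cls in RATE_CLASSES:
        if cls.name == name:
            return cls
    raise KeyError(f"unknown rate class {name!r}; known: {[c.name for c in RATE_CLASSES]}")


def interdose_swing(summary: SteadyStateSummary) -> float:
    """Absolute occupancy change across one steady-state interval (points)."""
    return summary.occ_at_cmax_percent - summary.occ_at_cmin_percent


def swing_from_concentrations(cmax_ng_ml: float, cmin_ng_ml: float,
                              params: DrugParams) -> float:
    """Swing implied by a (Cmax, Cmin) pair, e.g. printed reference values."""
    if cmax_ng_ml < cmin_ng_ml:
        raise ValueError("cmax must not be below cmin")
    hi = occupancy_from_concentration(cmax_ng_ml, params.emax_percent, params.ec50_ng_ml)
    lo = occupancy_from_concentration(cmin_ng_ml, params.emax_percent, params.ec50_ng_ml)
    return hi - lo


def abrupt_discontinuation_profile(dose_mg: float, interval_days: float,
                                   params: DrugParams, horizon_days: float = 400.0,
                                   profile_model: ProfileModel = DEFAULT_PROFILE_MODEL,
                                   step_days: float = 1.0) -> OccupancyProfile:
    """Occupancy tail after the final dose of an established regimen.

    Steady state on (dose, interval) is assumed; the last dose is given at
    day 0 and the superposed residual is followed for ``horizon_days``.
    """
    if horizon_days < MIN_HORIZON_DAYS:
        raise ValueError(
            f"horizon_days must be >= {MIN_HORIZON_DAYS:g} to cover the steep "
            f"post-discontinuation region, got {horizon_days}"
        )
    grid = day_grid(0.0, horizon_days, step_days)
    conc = steady_state_tail(dose_mg, interval_days, params, grid, profile_model)
    return occupancy_profile(conc, params)


def peak_window_drop(occ: OccupancyProfile, window_days: float = 30.0) -> float:
    """Largest occupancy decline over any ``window_days`` window (daily anchors)."""
    stride = max(int(round(1.0 / occ.step_days)), 1)
    w = int(round(window_days / occ.step_days))
    if w >= len(occ.values):
        raise ValueError("profile shorter than the requested window")
    v = occ.values
    drops = v[:-w:stride] - v[w::stride]
    return float(drops.max())


def peak_drop_terminal_limit(params: DrugParams, window_days: float = 30.0) -> float:
    """Closed-form peak window drop for a pure terminal-exponential tail.

    With concentration ``C0 * exp(-ke t)`` the occupancy is logistic in time,
    and the largest drop over a window of length w (attained symmetrically
    about half-maximal occupancy) is ``Emax * tanh(ke * w / 4)``. Starting
    occupancy must be high enough (>=80%) for the mid range to be traversed.
    """
    ke = params.ke_per_day
    return params.emax_percent * math.tanh(ke * window_days / 4.0)


def classify_rate(swing_points: float,
                  classes: tuple[RateClass, ...] = RATE_CLASSES) -> RateClass | str:
    """Slowest (most restrictive) class accommodating a swing; limits inclusive."""
    if swing_points < 0:
        raise ValueError("swing must be non-negative")
    for cls in sorted(classes, key=lambda c: c.limit_points):
        if swing_points <= cls.limit_points:
            return cls
    return "exceeds_all"
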