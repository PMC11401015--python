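"""Depot plasma-concentration model: single-dose profiles, superposition,
steady state and calibration.

Each injection contributes a dose-proportional single-dose profile
``C(t) = p * dose * g(t - t_dose)`` where ``g`` is a unit response normalised
to 1 at the single-dose peak (``g(tmax) = 1``) and ``p`` is the calibrated
"peak ng/ml per mg" scale. Two unit-response shapes are available:

``linear_rise`` (default)
    Linear absorption ramp up to the peak at ``tmax``, then pure exponential
    decay at the terminal rate ln2/half_life. This peak-then-decay shape
    reproduces the published 2-weekly steady-state peaks and troughs for
    these drugs to within ~2%.

``first_order``
    One-compartment first-order absorption (flip-flop style bi-exponential),
    with the absorption rate constant recovered from ``tmax`` via
    ``tmax = ln(ka/ke)/(ka - ke)``.

Multi-dose kinetics are plain superposition; steady state for periodic
dosing has an exact geometric-series closed form which is used everywhere
speed matters, with a cycle-by-cycle simulation kept as an independent
cross-check. The scale ``p`` is calibrated so that the simulated
steady-state peak of the drug's anchor regimen (a published Css,max at the
maximum licensed dose) matches the published value exactly.

Daily oral dosing is represented as a constant plasma level
(``oral_slope * dose``) held while dosing is active; with day-resolution
grids this is the only consistent reading of a linear daily-dose map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.optimize import brentq

from .occupancy import occupancy_from_concentration
from .params import DrugParams
from .profiles import ConcentrationProfile

__all__ = [
    "DoseEvent",
    "Regimen",
    "SteadyStateSummary",
    "ProfileModel",
    "DEFAULT_PROFILE_MODEL",
    "CalibrationError",
    "solve_absorption_rate",
    "calibrate_peak_per_mg",
    "single_dose_profile",
    "superpose",
    "steady_state_summary",
    "steady_state_tail",
    "day_grid",
    "unit_response",
]

ProfileModel = Literal["linear_rise", "first_order"]
DEFAULT_PROFILE_MODEL: ProfileModel = "linear_rise"

#: sub-grid (days) used to locate within-interval extrema
EXTREMA_STEP = 0.1
#: relative change in the within-cycle peak declaring simulated steady state
SS_REL_TOL = 1e-4
MAX_CYCLES = 50


class CalibrationError(RuntimeError):
    """Raised when a depot scale is requested but no anchor is configured."""


@dataclass(frozen=True)
class DoseEvent:
    """One administration on the model clock.

    Depot events contribute a single-dose profile from ``time_days`` onward;
    oral events contribute their constant mapped level for ``duration_days``
    (one day for a daily dose).
    """

    time_days: float
    dose_mg: float
    route: Literal["depot", "oral"] = "depot"
    duration_days: float = 1.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.time_days):
            raise ValueError("event time must be finite")
        if not math.isfinite(self.dose_mg) or self.dose_mg < 0:
            raise ValueError("dose_mg must be finite and non-negative")
        if self.route not in ("depot", "oral"):
            raise ValueError(f"unknown route {self.route!r}")
        if self.duration_days <= 0:
            raise ValueError("duration_days must be positive")


@dataclass(frozen=True)
class Regimen:
    """A repeating schedule that expands deterministically to dose events."""

    dose_mg: float
    interval_days: float
    route: Literal["depot", "oral"] = "depot"
    n_doses: int = 1
    start_day: float = 0.0

    def __post_init__(self) -> None:
        if self.interval_days <= 0:
            raise ValueError("interval_days must be positive")
        if self.n_doses < 1:
            raise ValueError("n_doses must be at least 1")

    def events(self) -> list[DoseEvent]:
        dur = self.interval_days if self.route == "oral" else 1.0
        return [
            DoseEvent(self.start_day + k * self.interval_days, self.dose_mg,
                      self.route, duration_days=dur)
            for k in range(self.n_doses)
        ]

    @property
    def label(self) -> str:
        return f"{self.dose_mg:g} mg {self.interval_days:g}-daily ({self.route})"


@dataclass(frozen=True)
class SteadyStateSummary:
    """Peak/trough concentrations and occupancies for one (dose, interval)."""

    drug: str
    dose_mg: float
    interval_days: float
    cmax_ng_ml: float
    cmin_ng_ml: float
    occ_at_cmax_percent: float
    occ_at_cmin_percent: float
    swing_points: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.cmax_ng_ml < self.cmin_ng_ml:
            raise ValueError("cmax must not be below cmin")
        if math.isnan(self.swing_points):
            object.__setattr__(
                self, "swing_points",
                self.occ_at_cmax_percent - self.occ_at_cmin_percent,
            )


def solve_absorption_rate(ke: float, tmax_days: float) -> float:
    """Absorption rate constant ka (1/day) with peak at ``tmax_days``.

    Solves ``tmax = ln(ka/ke)/(ka - ke)`` for the unique root ka > ke by
    bracketed root finding; the returned ka always exceeds ke (the peak must
    precede the terminal phase for a finite tmax).
    """
    if ke <= 0 or tmax_days <= 0:
        raise ValueError("ke and tmax_days must be positive")

    def f(ka: float) -> float:
        return math.log(ka / ke) / (ka - ke) - tmax_days

    lo, hi = ke * (1 + 1e-6), 1e3
    if f(lo) * f(hi) > 0:
        raise ValueError(
            f"no absorption rate in ({lo:.4g}, {hi:.4g}) yields tmax={tmax_days}"
        )
    return float(brentq(f, lo, hi, rtol=1e-12, maxiter=200))


# ---------------------------------------------------------------------------
# unit response and closed-form steady state


@lru_cache(maxsize=64)
def _rates(params: DrugParams, profile_model: ProfileModel) -> tuple[float, float | None]:
    ke = params.ke_per_day
    if profile_model == "first_order":
        return ke, solve_absorption_rate(ke, params.tmax_days)
    if profile_model == "linear_rise":
        return ke, None
    raise ValueError(f"unknown profile_model {profile_model!r}")


def unit_response(t, params: DrugParams,
                  profile_model: ProfileModel = DEFAULT_PROFILE_MODEL) -> np.ndarray:
    """Normalised single-dose shape g(t); g(tmax)=1, g=0 before the dose."""
    t = np.asarray(t, dtype=float)
    ke, ka = _rates(params, profile_model)
    tm = params.tmax_days
    if profile_model == "first_order":
        norm = math.exp(-ke * tm) - math.exp(-ka * tm)
        tt = np.maximum(t, 0.0)
        g = (np.exp(-ke * tt) - np.exp(-ka * tt)) / norm
        return np.where(t <= 0, 0.0, g)
    rising = t / tm
    decaying = np.exp(-ke * np.maximum(t - tm, 0.0))
    return np.where(t <= 0, 0.0, np.where(t < tm, rising, decaying))


def _steady_state_unit(t, interval_days: float, params: DrugParams,
                       profile_model: ProfileModel) -> np.ndarray:
    """Exact sum of g(t + n*tau) over all past doses n >= 0, for t >= 0.

    Evaluated inside one interval this is the periodic steady-state unit
    profile; evaluated on t beyond the interval it is the residual tail after
    the final dose of an established regimen (abrupt discontinuation).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("steady-state evaluation requires t >= 0")
    tau = float(interval_days)
    ke, ka = _rates(params, profile_model)
    tm = params.tmax_days
    if profile_model == "first_order":
        norm = math.exp(-ke * tm) - math.exp(-ka * tm)
        return (
            np.exp(-ke * t) / (1.0 - math.exp(-ke * tau))
            - np.exp(-ka * t) / (1.0 - math.exp(-ka * tau))
        ) / norm
    # linear_rise: doses still absorbing contribute their ramp, all older
    # doses form a geometric exponential tail
    n0 = np.ceil(np.maximum((tm - t) / tau, 0.0))
    ramp = np.where(n0 > 0, (n0 * t + tau * n0 * (n0 - 1) / 2.0) / tm, 0.0)
    tail_age = t + n0 * tau - tm
    tail = np.exp(-ke * tail_age) / (1.0 - math.exp(-ke * tau))
    return ramp + tail


def _interval_grid(interval_days: float) -> np.ndarray:
    n = int(round(interval_days / EXTREMA_STEP))
    return np.linspace(0.0, interval_days, n + 1)


@lru_cache(maxsize=64)
def calibrate_peak_per_mg(params: DrugParams,
                          profile_model: ProfileModel = DEFAULT_PROFILE_MODEL) -> float:
    """Depot scale p (peak ng/ml per mg of a single dose).

    Chosen so the steady-state peak of the anchor regimen equals the
    published Css,max; the peak is linear in p, so the solve is a single
    division after a unit-scale steady-state evaluation.
    """
    anchor = params.depot_anchor
    if anchor is None:
        raise CalibrationError(
            f"{params.name}: no depot_anchor configured; cannot calibrate the depot scale"
        )
    t = _interval_grid(anchor.interval_days)
    unit_peak = float(np.max(_steady_state_unit(t, anchor.interval_days, params, profile_model)))
    return anchor.css_max_ng_ml / (anchor.dose_mg * unit_peak)


def day_grid(start_day: float, stop_day: float, step_days: float = 1.0) -> np.ndarray:
    """Uniform time grid [start, stop] inclusive of the endpoint."""
    n = int(round((stop_day - start_day) / step_days))
    return start_day + step_days * np.arange(n + 1)


def single_dose_profile(dose_mg: float, params: DrugParams, grid: np.ndarray,
                        t_dose: float = 0.0,
                        profile_model: ProfileModel = DEFAULT_PROFILE_MODEL,
                        ) -> ConcentrationProfile:
    """Concentration trajectory of one depot injection on a uniform grid."""
    grid = np.asarray(grid, dtype=float)
    p = calibrate_peak_per_mg(params, profile_model)
    values = p * dose_mg * unit_response(grid - t_dose, params, profile_model)
    step = float(grid[1] - grid[0]) if len(grid) > 1 else 1.0
    return ConcentrationProfile(float(grid[0]), step, values)


def superpose(events: Iterable[DoseEvent | Regimen], params: DrugParams,
              grid: np.ndarray,
              profile_model: ProfileModel = DEFAULT_PROFILE_MODEL,
              ) -> ConcentrationProfile:
    """Pointwise sum of per-event contributions on a uniform grid.

    Depot events add calibrated single-dose profiles; oral events add their
    constant mapped level (``oral_slope * dose_mg``) over their duration.
    """
    grid = np.asarray(grid, dtype=float)
    flat: list[DoseEvent] = []
    for ev in events:
        flat.extend(ev.events() if isinstance(ev, Regimen) else [ev])
    flat.sort(key=lambda e: e.time_days)

    total = np.zeros_like(grid)
    depot = [e for e in flat if e.route == "depot"]
    if depot:
        p = calibrate_peak_per_mg(params, profile_model)
        for ev in depot:
            total += p * ev.dose_mg * unit_response(grid - ev.time_days, params, profile_model)
    for ev in flat:
        if ev.route == "oral":
            active = (grid >= ev.time_days) & (grid < ev.time_days + ev.duration_days)
            total += np.where(active, params.oral_slope_ng_ml_per_mg * ev.dose_mg, 0.0)
    step = float(grid[1] - grid[0]) if len(grid) > 1 else 1.0
    return ConcentrationProfile(float(grid[0]), step, total)


def _simulated_steady_state(dose_mg: float, interval_days: float, params: DrugParams,
                            profile_model: ProfileModel) -> np.ndarray:
    """Accumulate dosing cycles until the within-cycle peak stabilises."""
    t = _interval_grid(interval_days)
    p = calibrate_peak_per_mg(params, profile_model)
    profile = np.zeros_like(t)
    last_peak = np.inf
    for cycle in range(MAX_CYCLES):
        profile += p * dose_mg * unit_response(t + cycle * interval_days, params, profile_model)
        peak = float(profile.max())
        if abs(peak - last_peak) <= SS_REL_TOL * peak:
            return profile
        last_peak = peak
    raise RuntimeError(
        f"steady state not reached within {MAX_CYCLES} cycles "
        f"(dose={dose_mg}, interval={interval_days})"
    )


def steady_state_summary(dose_mg: float, interval_days: float, params: DrugParams,
                         profile_model: ProfileModel = DEFAULT_PROFILE_MODEL,
                         method: Literal["closed_form", "simulate"] = "closed_form",
                         ) -> SteadyStateSummary:
    """Steady-state Cmax/Cmin (0.1-day sub-grid) and their occupancies.

    ``closed_form`` evaluates the exact geometric-series steady state;
    ``simulate`` superposes repeated doses until the within-cycle peak
    changes by <0.01% between cycles. The two agree to well under 0.05%.
    """
    if dose_mg <= 0 or interval_days <= 0:
        raise ValueError("dose and interval must be positive")
    if method == "closed_form":
        t = _interval_grid(interval_days)
        p = calibrate_peak_per_mg(params, profile_model)
        profile = p * dose_mg * _steady_state_unit(t, interval_days, params, profile_model)
    elif method == "simulate":
        profile = _simulated_steady_state(dose_mg, interval_days, params, profile_model)
    else:
        raise ValueError(f"unknown method {method!r}")
    cmax = float(profile.max())
    cmin = float(profile.min())
    occ_max = occupancy_from_concentration(cmax, params.emax_percent, params.ec50_ng_ml)
    occ_min = occupancy_from_concentration(cmin, params.emax_percent, params.ec50_ng_ml)
    return SteadyStateSummary(
        drug=params.name, dose_mg=dose_mg, interval_days=interval_days,
        cmax_ng_ml=cmax, cmin_ng_ml=cmin,
        occ_at_cmax_percent=occ_max, occ_at_cmin_percent=occ_min,
    )


def steady_state_tail(dose_mg: float, interval_days: float, params: DrugParams,
                      grid: np.ndarray,
                      profile_model: ProfileModel = DEFAULT_PROFILE_MODEL,
                      ) -> ConcentrationProfile:
    """Residual concentration after the final dose of an established regimen.

    The final dose is given at day 0 with the full periodic dosing history
    behind it; the trajectory on ``grid`` (days >= 0) is the superposed tail.
    """
    grid = np.asarray(grid, dtype=float)
    p = calibrate_peak_per_mg(params, profile_model)
    values = p * dose_mg * _steady_state_unit(grid, interval_days, params, profile_model)
    step = float(grid[1] - grid[0]) if len(grid) > 1 else 1.0
    return ConcentrationProfile(float(grid[0]), step, values)
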