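"""Taper design: threshold doses, practical rounding, oral switch, full plans.

The decision logic mirrors how these depots are deprescribed in practice:

1. Find the lowest depot dose whose steady-state inter-dose occupancy swing
   stays within the chosen taper-rate class (searching the descending branch
   above the swing-maximising dose; swing vanishes at both very high doses,
   where occupancy saturates, and very low doses, where the Emax curve is
   locally linear).
2. Round that threshold up to the practical ampoule grid (0.2 ml steps of
   the lowest-strength preparation).
3. Reduce to the threshold in a single step — the residual of previous
   higher doses smooths the transition — and hold until the new steady
   state is established (about four half-lives, ~3 months).
4. When the next injection would be due, switch to a daily oral dose whose
   constant plasma level matches the depot trough occupancy; hold 2 months
   while the residual depot washes out.
5. Reduce the oral dose monthly so that each step lowers occupancy by the
   class rate (equal occupancy decrements require hyperbolically decreasing
   doses, via the inverse Emax transform), stopping with a final step to
   zero once occupancy is within one step of zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .occupancy import concentration_from_occupancy, occupancy_from_concentration, occupancy_profile
from .params import DrugParams, oral_level
from .pk import (
    DEFAULT_PROFILE_MODEL,
    DoseEvent,
    ProfileModel,
    Regimen,
    SteadyStateSummary,
    day_grid,
    steady_state_summary,
    superpose,
)
from .profiles import OccupancyProfile
from .rodoc import RateClass, interdose_swing, peak_window_drop, rate_class

__all__ = [
    "ThresholdResult",
    "OralSwitchResult",
    "TaperPhase",
    "TaperPlan",
    "PlanVerification",
    "round_up_to_increment",
    "threshold_dose",
    "oral_switch_dose",
    "build_taper_plan",
    "simulate_plan",
    "verify_plan",
]

#: continuous-dose bisection tolerance (mg)
DOSE_TOL_MG = 0.1
#: "3 months" depot consolidation: injections continue across this many days
DEPOT_HOLD_DAYS = 91.0
#: "2 months" oral consolidation before monthly reductions start
ORAL_HOLD_DAYS = 61.0
#: monthly reduction cadence (days)
ORAL_STEP_DAYS = 30.0
#: plans standardise on 2-weekly depot dosing before the oral switch
PLAN_DEPOT_INTERVAL = 14.0


@dataclass(frozen=True)
class ThresholdResult:
    """Lowest constraint-compatible depot dose for one (drug, interval, class).

    ``feasible`` is False when even the maximum licensed dose violates the
    class limit (no doses are then carried). ``binding`` is False when no
    dose violates the limit at this interval, in which case the threshold
    collapses to the smallest practical grid dose.
    """

    drug: str
    interval_days: float
    rate_class: RateClass
    raw_dose_mg: float | None
    rounded_dose_mg: float | None
    feasible: bool
    binding: bool = True
    summary: SteadyStateSummary | None = None


@dataclass(frozen=True)
class OralSwitchResult:
    """Daily oral dose continuing a taper past the depot threshold."""

    drug: str
    dose_mg: float
    level_ng_ml: float
    occupancy_percent: float
    verified: bool
    max_window_drop_points: float


@dataclass(frozen=True)
class TaperPhase:
    kind: str  # depot_reduce | depot_hold | oral_start | oral_hold | oral_step | stop
    start_day: float
    duration_days: float
    dose_mg: float
    route: str
    interval_days: float

    @property
    def end_day(self) -> float:
        return self.start_day + self.duration_days


@dataclass(frozen=True)
class TaperPlan:
    """Ordered, contiguous phases from an established regimen down to zero."""

    drug: str
    rate_class: RateClass
    start_dose_mg: float
    start_interval_days: float
    phases: tuple[TaperPhase, ...]

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("a plan needs at least one phase")
        for a, b in zip(self.phases, self.phases[1:]):
            if not math.isclose(a.end_day, b.start_day, abs_tol=1e-9):
                raise ValueError("plan phases must be contiguous in time")
        last = self.phases[-1]
        if last.kind != "stop" or last.dose_mg != 0:
            raise ValueError("final phase must be a stop at dose 0")

    @property
    def end_day(self) -> float:
        return self.phases[-1].start_day

    def dose_events(self, history_half_lives: float = 12.0,
                    params: DrugParams | None = None) -> list[DoseEvent]:
        """Expand the plan (plus pre-plan steady-state history) to events."""
        events: list[DoseEvent] = []
        # history of the previous regimen establishing steady state
        if params is not None:
            n_hist = int(math.ceil(history_half_lives * params.half_life_days
                                   / self.start_interval_days))
            t0 = min(ph.start_day for ph in self.phases)
            for k in range(1, n_hist + 1):
                events.append(DoseEvent(t0 - k * self.start_interval_days,
                                        self.start_dose_mg, "depot"))
        for ph in self.phases:
            if ph.dose_mg <= 0 or ph.duration_days <= 0:
                continue
            if ph.route == "depot":
                t = ph.start_day
                while t < ph.end_day - 1e-9:
                    events.append(DoseEvent(t, ph.dose_mg, "depot"))
                    t += ph.interval_days
            else:
                events.append(DoseEvent(ph.start_day, ph.dose_mg, "oral",
                                        duration_days=ph.duration_days))
        return events

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "phase": ph.kind,
                    "start_day": ph.start_day,
                    "duration_days": ph.duration_days,
                    "dose_mg": ph.dose_mg,
                    "route": ph.route,
                    "interval_days": ph.interval_days,
                }
                for ph in self.phases
            ]
        )

    def to_text(self) -> str:
        lines = [f"{self.drug} taper ({self.rate_class.name}, "
                 f"limit {self.rate_class.limit_points:g} points):",
                 f"- Starting regimen: {self.start_dose_mg:g} mg "
                 f"{self.start_interval_days:g}-day depot."]
        for ph in self.phases:
            if ph.kind == "depot_reduce":
                lines.append(f"- Reduce to {ph.dose_mg:g} mg every "
                             f"{ph.interval_days:g} days (depot).")
            elif ph.kind == "depot_hold":
                lines.append(f"- Maintain {ph.dose_mg:g} mg every "
                             f"{ph.interval_days:g} days for {ph.duration_days:g} days.")
            elif ph.kind == "oral_start":
                lines.append(f"- When the next depot dose is due (day "
                             f"{ph.start_day:g}), commence {ph.dose_mg:g} mg "
                             f"oral daily.")
            elif ph.kind == "oral_hold":
                lines.append(f"- Maintain {ph.dose_mg:g} mg oral daily for "
                             f"{ph.duration_days:g} days.")
            elif ph.kind == "oral_step":
                lines.append(f"- Day {ph.start_day:g}: reduce oral dose to "
                             f"{ph.dose_mg:.3g} mg daily.")
            elif ph.kind == "stop":
                lines.append(f"- Day {ph.start_day:g}: stop.")
        return "\n".join(lines)


@dataclass(frozen=True)
class PlanVerification:
    """Largest 30-day occupancy decline observed over a simulated plan."""

    limit_points: float
    max_drop_points: float
    day_of_max: float
    tolerance_points: float = 0.5

    @property
    def compliant(self) -> bool:
        return self.max_drop_points <= self.limit_points + self.tolerance_points


def round_up_to_increment(dose_mg: float, params: DrugParams) -> float:
    """Next practical depot dose at or above ``dose_mg``.

    The increment band is selected by the unrounded dose; at exactly a band
    boundary the lower band applies.
    """
    if dose_mg <= 0:
        raise ValueError("dose must be positive")
    for band in params.depot_increments:
        if dose_mg <= band.upper_dose_mg:
            inc = band.increment_mg
            k = math.ceil(dose_mg / inc - 1e-9)
            return k * inc
    raise ValueError(f"dose {dose_mg} above all increment bands")  # pragma: no cover


def _swing(dose_mg: float, interval_days: float, params: DrugParams,
           profile_model: ProfileModel) -> float:
    return interdose_swing(
        steady_state_summary(dose_mg, interval_days, params, profile_model)
    )


def threshold_dose(params: DrugParams, interval_days: float,
                   rate: RateClass | float,
                   profile_model: ProfileModel = DEFAULT_PROFILE_MODEL,
                   ) -> ThresholdResult:
    """Smallest depot dose whose steady-state swing stays within a limit.

    The swing is non-monotone in dose (it vanishes both at saturating doses
    and near zero), so the search is restricted to the descending-dose
    branch above the swing-maximising dose and solved by bisection to 0.1 mg
    before rounding up to the practical grid. Infeasibility (even the
    maximum licensed dose violates the limit) is a result, not an error.
    """
    cls = rate if isinstance(rate, RateClass) else RateClass("custom", float(rate))
    if cls.limit_points <= 0:
        raise ValueError("rate limit must be positive")
    dmax = params.max_licensed.dose_mg
    if _swing(dmax, interval_days, params, profile_model) > cls.limit_points:
        return ThresholdResult(params.name, interval_days, cls,
                               raw_dose_mg=None, rounded_dose_mg=None,
                               feasible=False)
    # locate the swing-maximising dose (unimodal in log dose)
    res = minimize_scalar(
        lambda ld: -_swing(math.exp(ld), interval_days, params, profile_model),
        bounds=(math.log(1e-3), math.log(dmax)), method="bounded",
        options={"xatol": 1e-4},
    )
    d_star, peak_swing = math.exp(res.x), -res.fun
    if peak_swing <= cls.limit_points:
        # the constraint never binds at this interval
        rounded = params.depot_increments[0].increment_mg
        summary = steady_state_summary(rounded, interval_days, params, profile_model)
        return ThresholdResult(params.name, interval_days, cls,
                               raw_dose_mg=0.0, rounded_dose_mg=rounded,
                               feasible=True, binding=False, summary=summary)
    lo, hi = d_star, dmax
    while hi - lo > DOSE_TOL_MG:
        mid = 0.5 * (lo + hi)
        if _swing(mid, interval_days, params, profile_model) <= cls.limit_points:
            hi = mid
        else:
            lo = mid
    rounded = min(round_up_to_increment(hi, params), dmax)
    summary = steady_state_summary(rounded, interval_days, params, profile_model)
    return ThresholdResult(params.name, interval_days, cls,
                           raw_dose_mg=hi, rounded_dose_mg=rounded,
                           feasible=True, summary=summary)


def _round_nearest(value: float, increment: float) -> float:
    return math.floor(value / increment + 0.5) * increment


def oral_switch_dose(params: DrugParams, depot_dose_mg: float,
                     depot_interval_days: float, rate: RateClass,
                     transition_allowance_points: float = 0.0,
                     profile_model: ProfileModel = DEFAULT_PROFILE_MODEL,
                     verify_horizon_days: float = 200.0,
                     verify_tolerance_points: float = 0.5,
                     ) -> OralSwitchResult:
    """Daily oral dose matching the depot trough occupancy (minus allowance).

    The steady-state trough occupancy of the depot regimen is inverted to a
    plasma level, divided by the oral slope and rounded to the practical
    oral increment. The combined switch (residual depot plus constant oral)
    is then simulated and the largest 30-day occupancy decline compared to
    the class limit; ``verified`` is False when even the trough-matched dose
    cannot keep the washout within the limit.
    """
    summary = steady_state_summary(depot_dose_mg, depot_interval_days, params,
                                   profile_model)
    target_occ = summary.occ_at_cmin_percent - transition_allowance_points
    if target_occ <= 0:
        raise ValueError("transition allowance exceeds the depot trough occupancy")
    level = concentration_from_occupancy(target_occ, params.emax_percent,
                                         params.ec50_ng_ml)
    dose = _round_nearest(level / params.oral_slope_ng_ml_per_mg,
                          params.oral_increment_mg)
    dose = max(dose, params.oral_increment_mg)  # an oral switch implies a nonzero dose

    # simulate the combined switch: established depot regimen stops after a
    # final dose at day 0, oral starts when the next injection would be due
    from .pk import steady_state_tail  # local import avoids cycle at module load

    grid = day_grid(0.0, verify_horizon_days, 0.25)
    tail = steady_state_tail(depot_dose_mg, depot_interval_days, params, grid,
                             profile_model)
    oral = np.where(grid >= depot_interval_days,
                    oral_level(dose, params), 0.0)
    from .profiles import ConcentrationProfile

    combined = ConcentrationProfile(0.0, 0.25, tail.values + oral)
    occ = occupancy_profile(combined, params)
    max_drop = peak_window_drop(occ, 30.0)
    verified = max_drop <= rate.limit_points + verify_tolerance_points
    actual_level = oral_level(dose, params)
    return OralSwitchResult(
        drug=params.name, dose_mg=dose, level_ng_ml=actual_level,
        occupancy_percent=occupancy_from_concentration(
            actual_level, params.emax_percent, params.ec50_ng_ml),
        verified=verified, max_window_drop_points=max_drop,
    )


def _oral_step_doses(start_occ: float, rate_points: float, params: DrugParams,
                     step_grid_mg: float | None) -> list[float]:
    """Hyperbolic dose sequence giving equal occupancy decrements.

    Steps down by exactly ``rate_points`` while the target occupancy stays
    positive; once occupancy is within one step of zero the sequence ends
    (the caller appends the final step to zero). Doses are optionally
    snapped to a fine practical grid with strict monotonic decrease.
    """
    doses: list[float] = []
    occ = start_occ
    prev = math.inf
    while occ - rate_points > 0:
        occ -= rate_points
        dose = concentration_from_occupancy(
            occ, params.emax_percent, params.ec50_ng_ml
        ) / params.oral_slope_ng_ml_per_mg
        if step_grid_mg is not None:
            dose = _round_nearest(dose, step_grid_mg)
            if dose >= prev:
                dose = prev - step_grid_mg
            if dose <= 0:
                break
        doses.append(dose)
        prev = dose
    return doses


def build_taper_plan(params: DrugParams, start_dose_mg: float,
                     start_interval_days: float, rate: RateClass | str,
                     profile_model: ProfileModel = DEFAULT_PROFILE_MODEL,
                     step_grid_mg: float | None = None,
                     ) -> TaperPlan:
    """Assemble a complete depot-to-zero taper plan for one rate class.

    The depot is reduced in a single step to the 2-weekly threshold dose
    (residual elimination of the previous higher doses makes intermediate
    depot steps unnecessary), held ~3 months, switched to a trough-matched
    daily oral dose when the next injection would be due, held 2 months,
    then reduced monthly in equal occupancy decrements down to zero. If the
    starting regimen is already at or below the threshold, the plan begins
    directly at the oral switch.
    """
    cls = rate if isinstance(rate, RateClass) else rate_class(rate)
    thr = threshold_dose(params, PLAN_DEPOT_INTERVAL, cls, profile_model)
    if not thr.feasible:
        raise ValueError(
            f"{params.name}: no 2-weekly depot dose satisfies the "
            f"{cls.name} limit; taper cannot start in depot form"
        )
    phases: list[TaperPhase] = []
    at_threshold = (
        math.isclose(start_interval_days, PLAN_DEPOT_INTERVAL)
        and start_dose_mg <= thr.rounded_dose_mg + 1e-9
    )
    if at_threshold:
        depot_dose = start_dose_mg
        # final scheduled injection happens at day 0; oral follows next due date
        phases.append(TaperPhase("depot_hold", 0.0, start_interval_days,
                                 depot_dose, "depot", start_interval_days))
        switch_day = start_interval_days
        switch_interval = start_interval_days
    else:
        depot_dose = thr.rounded_dose_mg
        n_cycles = int(math.ceil(DEPOT_HOLD_DAYS / PLAN_DEPOT_INTERVAL))
        switch_day = n_cycles * PLAN_DEPOT_INTERVAL
        phases.append(TaperPhase("depot_reduce", 0.0, PLAN_DEPOT_INTERVAL,
                                 depot_dose, "depot", PLAN_DEPOT_INTERVAL))
        phases.append(TaperPhase("depot_hold", PLAN_DEPOT_INTERVAL,
                                 switch_day - PLAN_DEPOT_INTERVAL,
                                 depot_dose, "depot", PLAN_DEPOT_INTERVAL))
        switch_interval = PLAN_DEPOT_INTERVAL

    switch = oral_switch_dose(params, depot_dose, switch_interval, cls,
                              profile_model=profile_model)
    phases.append(TaperPhase("oral_start", switch_day, 0.0,
                             switch.dose_mg, "oral", 1.0))
    phases.append(TaperPhase("oral_hold", switch_day, ORAL_HOLD_DAYS,
                             switch.dose_mg, "oral", 1.0))
    t = switch_day + ORAL_HOLD_DAYS
    for dose in _oral_step_doses(switch.occupancy_percent, cls.limit_points,
                                 params, step_grid_mg):
        phases.append(TaperPhase("oral_step", t, ORAL_STEP_DAYS, dose, "oral", 1.0))
        t += ORAL_STEP_DAYS
    phases.append(TaperPhase("stop", t, 0.0, 0.0, "oral", 1.0))
    return TaperPlan(params.name, cls, start_dose_mg, start_interval_days,
                     tuple(phases))


def simulate_plan(plan: TaperPlan, params: DrugParams,
                  profile_model: ProfileModel = DEFAULT_PROFILE_MODEL,
                  step_days: float = 0.25,
                  tail_days: float = 60.0) -> OccupancyProfile:
    """Occupancy trajectory of a plan from start to past the last dose.

    The pre-plan history of the starting regimen is included so the
    trajectory begins at that regimen's steady state; depot residuals and
    constant oral contributions superpose.
    """
    events = plan.dose_events(params=params)
    last_dose_day = max(
        (ev.time_days for ev in events if ev.dose_mg > 0), default=0.0
    )
    grid = day_grid(0.0, max(plan.end_day, last_dose_day) + tail_days, step_days)
    conc = superpose(events, params, grid, profile_model)
    return occupancy_profile(conc, params)


def verify_plan(plan: TaperPlan, params: DrugParams,
                profile_model: ProfileModel = DEFAULT_PROFILE_MODEL,
                tolerance_points: float = 0.5) -> PlanVerification:
    """Check a simulated plan against its own 30-day rate limit."""
    occ = simulate_plan(plan, params, profile_model)
    stride = max(int(round(1.0 / occ.step_days)), 1)
    w = int(round(30.0 / occ.step_days))
    v = occ.values
    drops = v[:-w:stride] - v[w::stride]
    imax = int(np.argmax(drops))
    return PlanVerification(
        limit_points=plan.rate_class.limit_points,
        max_drop_points=float(drops[imax]),
        day_of_max=float(occ.start_day + imax * stride * occ.step_days),
        tolerance_points=tolerance_points,
    )
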