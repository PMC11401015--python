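"""Depot kinetics: absorption solve, single-dose shape, superposition,
calibration and steady state."""

import math

import numpy as np
import pytest

from lidataper import (
    DoseEvent,
    Regimen,
    calibrate_peak_per_mg,
    day_grid,
    default_drug_params,
    single_dose_profile,
    solve_absorption_rate,
    steady_state_summary,
    superpose,
)
from lidataper.params import DrugParams
from lidataper.pk import CalibrationError, unit_response
import dataclasses


def _bisect_tmax_equation(ke, tmax, lo=None, hi=1e3, iters=200):
    """Independent bisection oracle for tmax = ln(ka/ke)/(ka - ke)."""
    lo = lo or ke * (1 + 1e-9)
    f = lambda ka: math.log(ka / ke) / (ka - ke) - tmax
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f(lo) * f(mid) <= 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


@pytest.mark.parametrize("half_life, tmax", [(17.0, 7.0), (20.0, 7.0), (19.0, 7.0),
                                             (30.0, 3.0), (5.0, 1.0)])
def test_absorption_rate_matches_bisection_oracle(half_life, tmax):
    ke = math.log(2) / half_life
    ka = solve_absorption_rate(ke, tmax)
    assert ka == pytest.approx(_bisect_tmax_equation(ke, tmax), rel=1e-8)
    assert ka > ke
    # the recovered ka indeed peaks the bi-exponential at tmax
    assert math.log(ka / ke) / (ka - ke) == pytest.approx(tmax, rel=1e-10)


def test_absorption_rate_frozen_values():
    # bisection-oracle values for the shipped half-life/tmax combinations
    assert solve_absorption_rate(math.log(2) / 17, 7.0) == pytest.approx(0.34644, abs=1e-4)
    assert solve_absorption_rate(math.log(2) / 20, 7.0) == pytest.approx(0.37477, abs=1e-4)


@pytest.mark.parametrize("profile_model", ["linear_rise", "first_order"])
def test_single_dose_profile_normalisation(flupentixol, profile_model):
    grid = day_grid(0.0, 150.0, 0.5)
    prof = single_dose_profile(100.0, flupentixol, grid, profile_model=profile_model)
    p = calibrate_peak_per_mg(flupentixol, profile_model)
    # peak equals p * dose exactly at tmax, zero at the dose time, positive after
    assert prof.at(flupentixol.tmax_days) == pytest.approx(100.0 * p, rel=1e-12)
    assert prof.values[0] == 0.0
    assert np.all(prof.values[1:] > 0)
    assert np.max(prof.values) == pytest.approx(100.0 * p, rel=1e-9)


@pytest.mark.parametrize("profile_model", ["linear_rise", "first_order"])
def test_terminal_slope_recovers_half_life(haloperidol, profile_model):
    grid = day_grid(0.0, 130.0, 1.0)
    prof = single_dose_profile(50.0, haloperidol, grid, profile_model=profile_model)
    sel = (grid >= 60) & (grid <= 120)
    slope = np.polyfit(grid[sel], np.log(prof.values[sel]), 1)[0]
    assert -math.log(2) / slope == pytest.approx(haloperidol.half_life_days, rel=1e-3)


def test_superpose_matches_bruteforce_single_doses(haloperidol):
    """Six monthly 300 mg doses equal the sum of six single-dose profiles."""
    grid = day_grid(0.0, 300.0, 1.0)
    reg = Regimen(300.0, 28.0, "depot", n_doses=6)
    combined = superpose([reg], haloperidol, grid)
    brute = sum(
        single_dose_profile(300.0, haloperidol, grid, t_dose=28.0 * k).values
        for k in range(6)
    )
    np.testing.assert_allclose(combined.values, brute, rtol=1e-12)


def test_superpose_oral_event_holds_constant_level(haloperidol):
    grid = day_grid(0.0, 10.0, 0.5)
    ev = DoseEvent(2.0, 10.0, "oral", duration_days=3.0)
    prof = superpose([ev], haloperidol, grid)
    active = (grid >= 2.0) & (grid < 5.0)
    assert np.all(prof.values[active] == pytest.approx(10.61, abs=1e-9))
    assert np.all(prof.values[~active] == 0.0)


def test_calibration_reproduces_anchor_peaks(all_drugs):
    """Steady state on each drug's anchor regimen hits the published Css,max."""
    for params in all_drugs.values():
        anchor = params.depot_anchor
        s = steady_state_summary(anchor.dose_mg, anchor.interval_days, params)
        assert s.cmax_ng_ml == pytest.approx(anchor.css_max_ng_ml, rel=1e-8)


def test_calibration_scales_linearly_with_anchor(flupentixol):
    doubled = dataclasses.replace(
        flupentixol,
        depot_anchor=dataclasses.replace(
            flupentixol.depot_anchor,
            css_max_ng_ml=2 * flupentixol.depot_anchor.css_max_ng_ml,
        ),
    )
    assert calibrate_peak_per_mg(doubled) == pytest.approx(
        2 * calibrate_peak_per_mg(flupentixol), rel=1e-12
    )


def test_uncalibrated_params_raise(flupentixol):
    bare = dataclasses.replace(flupentixol, depot_anchor=None)
    with pytest.raises(CalibrationError):
        single_dose_profile(100.0, bare, day_grid(0.0, 10.0))


@pytest.mark.parametrize("profile_model", ["linear_rise", "first_order"])
def test_closed_form_equals_simulated_steady_state(all_drugs, profile_model):
    """Geometric-series steady state agrees with cycle accumulation <0.05%."""
    for params in all_drugs.values():
        for dose, tau in [(200.0, 14.0), (300.0, 28.0), (400.0, 7.0)]:
            closed = steady_state_summary(dose, tau, params, profile_model,
                                          method="closed_form")
            sim = steady_state_summary(dose, tau, params, profile_model,
                                       method="simulate")
            assert sim.cmax_ng_ml == pytest.approx(closed.cmax_ng_ml, rel=5e-4)
            assert sim.cmin_ng_ml == pytest.approx(closed.cmin_ng_ml, rel=5e-4)


def test_steady_state_linear_in_dose(flupentixol):
    s1 = steady_state_summary(100.0, 14.0, flupentixol)
    s2 = steady_state_summary(200.0, 14.0, flupentixol)
    assert s2.cmax_ng_ml == pytest.approx(2 * s1.cmax_ng_ml, rel=1e-12)
    assert s2.cmin_ng_ml == pytest.approx(2 * s1.cmin_ng_ml, rel=1e-12)


def test_peak_trough_ratio_independent_of_dose(zuclopenthixol):
    ratios = [
        steady_state_summary(d, 21.0, zuclopenthixol).cmin_ng_ml
        / steady_state_summary(d, 21.0, zuclopenthixol).cmax_ng_ml
        for d in (50.0, 200.0, 600.0)
    ]
    assert max(ratios) - min(ratios) < 1e-12


def test_cycle_peaks_converge_monotonically(haloperidol):
    """Accumulating cycles raises the within-cycle peak toward steady state."""
    from lidataper.pk import _interval_grid, unit_response

    t = _interval_grid(28.0)
    profile = np.zeros_like(t)
    peaks = []
    for cycle in range(20):
        profile += unit_response(t + cycle * 28.0, haloperidol)
        peaks.append(profile.max())
    diffs = np.diff(peaks)
    assert np.all(diffs > 0)
    assert np.all(np.diff(diffs) < 0)  # geometric approach, shrinking gains
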