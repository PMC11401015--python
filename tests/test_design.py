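"""Threshold search, practical rounding, oral switch and taper plans."""

import math

import numpy as np
import pytest

from lidataper import (
    build_taper_plan,
    oral_switch_dose,
    rate_class,
    round_up_to_increment,
    simulate_plan,
    steady_state_summary,
    threshold_dose,
    verify_plan,
)
from lidataper.occupancy import concentration_from_occupancy


class TestRounding:
    @pytest.mark.parametrize(
        "dose, expected",
        [(21.3, 24.0), (61.0, 80.0), (58.0, 60.0), (60.0, 60.0), (4.0, 4.0)],
    )
    def test_flupentixol_bands(self, dose, expected, flupentixol):
        # 4 mg steps up to 60 mg (boundary inclusive), 20 mg steps above
        assert round_up_to_increment(dose, flupentixol) == expected

    def test_zuclopenthixol_on_grid(self, zuclopenthixol):
        assert round_up_to_increment(160.0, zuclopenthixol) == 160.0
        assert round_up_to_increment(160.1, zuclopenthixol) == 200.0

    def test_rejects_nonpositive(self, flupentixol):
        with pytest.raises(ValueError):
            round_up_to_increment(0.0, flupentixol)


class TestThresholdDose:
    def test_flupentixol_moderate_2weekly_near_published(self, flupentixol):
        thr = threshold_dose(flupentixol, 14.0, rate_class("moderate"))
        assert thr.feasible and thr.binding
        assert abs(thr.rounded_dose_mg - 24.0) <= 4.0  # within one increment
        assert thr.rounded_dose_mg >= thr.raw_dose_mg

    def test_zuclopenthixol_fast_4weekly_near_published(self, zuclopenthixol):
        thr = threshold_dose(zuclopenthixol, 28.0, rate_class("fast"))
        assert thr.feasible
        assert abs(thr.rounded_dose_mg - 400.0) <= 40.0

    def test_haloperidol_slow_4weekly_infeasible(self, haloperidol):
        thr = threshold_dose(haloperidol, 28.0, rate_class("slow"))
        assert not thr.feasible
        assert thr.raw_dose_mg is None and thr.rounded_dose_mg is None

    def test_huge_limit_never_binds(self, haloperidol):
        thr = threshold_dose(haloperidol, 14.0, 100.0)
        assert thr.feasible and not thr.binding
        assert thr.rounded_dose_mg == haloperidol.depot_increments[0].increment_mg

    def test_threshold_monotone_in_limit_and_interval(self, flupentixol):
        """Stricter limits and longer intervals both push the threshold up."""
        doses_by_limit = [
            threshold_dose(flupentixol, 14.0, lim).raw_dose_mg
            for lim in (5.0, 2.5, 1.25)
        ]
        assert doses_by_limit == sorted(doses_by_limit)
        doses_by_interval = [
            threshold_dose(flupentixol, tau, 5.0).raw_dose_mg
            for tau in (14.0, 21.0, 28.0)
        ]
        assert doses_by_interval == sorted(doses_by_interval)

    def test_threshold_regimen_satisfies_its_limit(self, all_drugs):
        for params in all_drugs.values():
            thr = threshold_dose(params, 14.0, rate_class("moderate"))
            assert thr.summary.swing_points <= 5.0 + 1e-6


class TestOralSwitch:
    def test_haloperidol_moderate_matches_published(self, haloperidol):
        """Trough matching the 40 mg 2-weekly depot gives 1.5 mg daily."""
        sw = oral_switch_dose(haloperidol, 40.0, 14.0, rate_class("moderate"))
        assert sw.dose_mg == pytest.approx(1.5)

    def test_haloperidol_fast_matches_published(self, haloperidol):
        sw = oral_switch_dose(haloperidol, 10.0, 14.0, rate_class("fast"))
        assert sw.dose_mg == pytest.approx(0.5)

    def test_trough_matching_arithmetic(self, haloperidol):
        """Unrounded chain: trough occupancy -> level -> dose / oral slope."""
        s = steady_state_summary(40.0, 14.0, haloperidol)
        level = concentration_from_occupancy(
            s.occ_at_cmin_percent, haloperidol.emax_percent, haloperidol.ec50_ng_ml
        )
        assert 70.0 < s.occ_at_cmin_percent < 80.0
        assert level == pytest.approx(1.6, abs=0.1)
        assert level / haloperidol.oral_slope_ng_ml_per_mg == pytest.approx(1.5, abs=0.1)

    def test_switch_reports_washout_drop(self, haloperidol):
        sw = oral_switch_dose(haloperidol, 40.0, 14.0, rate_class("moderate"))
        assert sw.max_window_drop_points > 0.0
        assert sw.level_ng_ml == pytest.approx(sw.dose_mg * 1.061)


class TestTaperPlan:
    def test_moderate_haloperidol_plan_structure(self, haloperidol):
        plan = build_taper_plan(haloperidol, 300.0, 28.0, "moderate")
        kinds = [ph.kind for ph in plan.phases]
        assert kinds[0] == "depot_reduce"
        assert kinds[-1] == "stop"
        assert "oral_start" in kinds and "oral_hold" in kinds
        reduce_phase = plan.phases[0]
        # single-step reduction to the 2-weekly threshold (within one
        # formulation increment of the published 40 mg)
        assert reduce_phase.interval_days == 14.0
        assert abs(reduce_phase.dose_mg - 40.0) <= 10.0
        # oral starts when the next depot dose would be due, after ~3 months
        oral_start = next(ph for ph in plan.phases if ph.kind == "oral_start")
        assert oral_start.start_day == pytest.approx(98.0)
        hold = next(ph for ph in plan.phases if ph.kind == "oral_hold")
        assert hold.duration_days == pytest.approx(61.0)

    def test_zuclopenthixol_moderate_first_phase_near_published(self, zuclopenthixol):
        plan = build_taper_plan(zuclopenthixol, 600.0, 7.0, "moderate")
        assert plan.phases[0].kind == "depot_reduce"
        assert abs(plan.phases[0].dose_mg - 80.0) <= 40.0

    def test_start_at_threshold_skips_depot_reduction(self, haloperidol):
        thr = threshold_dose(haloperidol, 14.0, rate_class("moderate"))
        plan = build_taper_plan(haloperidol, thr.rounded_dose_mg, 14.0, "moderate")
        assert all(ph.kind != "depot_reduce" for ph in plan.phases)

    def test_oral_steps_give_equal_occupancy_decrements(self, haloperidol):
        from lidataper.occupancy import occupancy_from_concentration

        plan = build_taper_plan(haloperidol, 300.0, 28.0, "moderate")
        steps = [ph.dose_mg for ph in plan.phases if ph.kind == "oral_step"]
        assert steps == sorted(steps, reverse=True)
        occs = [
            occupancy_from_concentration(d * 1.061, 100.0, 0.51) for d in steps
        ]
        decrements = -np.diff(occs)
        np.testing.assert_allclose(decrements, 5.0, atol=1e-9)
        # hyperbolic pattern: dose sequence is convex (decreasing steps sizes)
        assert np.all(np.diff(steps, 2) > 0)

    def test_plan_simulation_starts_at_steady_state_and_is_continuous(
        self, haloperidol
    ):
        plan = build_taper_plan(haloperidol, 300.0, 28.0, "moderate")
        occ = simulate_plan(plan, haloperidol)
        s = steady_state_summary(300.0, 28.0, haloperidol)
        assert s.occ_at_cmin_percent - 0.5 <= occ.values[0] <= s.occ_at_cmax_percent + 0.5
        # declines are smooth apart from the designed oral-step reductions,
        # each of which drops occupancy by at most the class rate
        assert np.min(np.diff(occ.values)) >= -(plan.rate_class.limit_points + 0.1)
        assert occ.values[-1] < 1.0

    def test_plan_verification_reports_transition_washout(self, haloperidol):
        """The oral-switch washout is the rate-limiting stretch of the plan."""
        plan = build_taper_plan(haloperidol, 300.0, 28.0, "moderate")
        check = verify_plan(plan, haloperidol)
        assert check.max_drop_points > plan.rate_class.limit_points
        oral_start = next(ph for ph in plan.phases if ph.kind == "oral_start")
        assert check.day_of_max < oral_start.start_day + 91.0

    def test_infeasible_limit_raises(self, haloperidol):
        from lidataper import RateClass

        # even the licensed maximum swings more than 0.5 points at 2-weekly
        with pytest.raises(ValueError):
            build_taper_plan(haloperidol, 300.0, 28.0, RateClass("custom", 0.5))
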