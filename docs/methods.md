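# Methods

## Scope and model structure

`lidataper` models decanoate-ester depot antipsychotics with a
single-compartment, dose-proportional superposition model on a time grid in
days. Absorption from the oily depot rate-limits the profile ("flip-flop"
kinetics), so the apparent elimination half-life t½ (17 d flupentixol, 20 d
haloperidol, 19 d zuclopenthixol) sets the terminal log-linear decay
`ke = ln2/t½`, and every drug peaks at `tmax = 7` days after injection.
Occupancy is equilibrium receptor binding only (Emax model, Emax fixed at
100% as in the underlying imaging studies; kept as a parameter); no binding
kinetics, no multi-compartment disposition, no between-patient variability.

## Single-dose shape and why the default is `linear_rise`

The published modelling this package reimplements was built in a
spreadsheet from "remaining proportion" half-life arithmetic, and its exact
per-interval equations are not recoverable. Two reconstructions are
provided:

* `linear_rise` (default): linear ramp to the peak at `tmax`, exponential
  decay afterwards.
* `first_order`: `g(t) ∝ e^(−ke·t) − e^(−ka·t)`, with `ka` solved from
  `tmax = ln(ka/ke)/(ka − ke)` by bracketed root finding (rtol 1e-12).

Calibrated against the published anchor peaks (Css,max at the maximum
licensed regimen), `linear_rise` reproduces the published 2-weekly
steady-state peak/trough values to within ±2%, while `first_order` misses
the 2-weekly peak by −7% (absorption overlap inflates the weekly anchor's
peak relative to 2-weekly regimens). Since every taper plan standardises on
the 2-weekly interval, `linear_rise` is the default.

Neither shape — nor any other single profile — can reproduce the published
3- and 4-weekly values. The published peaks for the same dose fall off with
interval faster than superposition allows: any profile with terminal rate
`ke` gives steady-state peak ratios bounded by the geometric accumulation
factors (for 14 d vs 28 d, ≤ ~1.56), whereas the published ratio is 2.12.
The published long-interval concentrations therefore embed information
(most plausibly per-frequency literature anchors) that a calibrated
single-dose model cannot carry. Consequences, reported honestly by the
validation suite and the `tables` diff report: simulated 3-/4-weekly
concentrations run +8–33% above the published values, and threshold doses
at those intervals land lower than the published ones (sometimes by more
than one ampoule increment, and three published "not possible" cells become
feasible). The 2-weekly column — the one plans use — agrees to within one
increment throughout.

## Steady state, calibration and numerical conventions

For periodic dosing the steady state is evaluated in closed form
(geometric series of the exponential tails plus the finitely many doses
still absorbing); a cycle-accumulation simulation with a <0.01% peak-change
stopping rule (error after 50 cycles) is kept as an independent cross-check
and agrees to <0.05%. Within-interval extrema are located on a 0.1-day
sub-grid; reporting grids are daily; plan simulations use 0.25-day steps.
The depot scale p ("peak ng/ml per mg") is the single division
`Css,max(anchor) / unit-dose steady-state peak`, exact because peaks are
linear in p. Doses contribute from the moment of injection with no lag, and
dose proportionality is assumed throughout. A dose at exactly a rounding
band boundary uses the lower band's increment.

## RODOC metrics

Occupancy-change rate is measured per inter-dose interval for dosed
regimens (steady-state peak minus trough occupancy) and per 30 days for
abrupt cessation (maximum decline over any 30-day window, daily anchors).
Class limits — 1.25/2.5/5/10 points — are inclusive. For a residual tail
decaying at `ke` through the mid-occupancy range, the peak 30-day drop has
the closed form `Emax·tanh(7.5·ln2/t½)`, used as an analytic oracle; the
simulation matches it to <0.01 points, and the value is independent of the
dose discontinued from provided starting occupancy is ≥80%.

## Threshold search

The swing-vs-dose curve vanishes at saturating doses (occupancy flat near
Emax) and at near-zero doses (Emax curve locally linear), with one interior
maximum. The threshold search brackets that maximum (bounded scalar
minimisation in log dose), declares infeasibility if the maximum licensed
dose itself violates the limit, returns the smallest grid dose when the
limit never binds, and otherwise bisects the descending branch to 0.1 mg
before rounding up to the ampoule grid (0.2 ml of the lowest-strength
preparation: 4/20 mg flupentixol, 10/20 mg haloperidol, 40 mg
zuclopenthixol).

## Taper plans and design choices that were genuinely open

* **Oral slope for flupentixol**: two published anchors exist (1.5 mg →
  0.495 ng/ml peak; 1 mg → 0.2 ng/ml trough). The peak-derived slope
  0.33 ng/ml/mg is the default (it reproduces the published moderate-class
  oral switch dose); the trough slope is retained as a named alternative in
  the config.
* **Timing**: "3 months" depot consolidation is realised as 2-weekly
  injections across 91 days (7 injections, days 0–84) with the oral switch
  at the next due date, day 98; "2 months" oral hold is 61 days; "monthly"
  reductions are every 30 days. The oral switch "when the next dose is due"
  is read as 14 days after the last injection, not after washout.
* **Oral switch dose**: trough matching (invert the depot trough occupancy
  through Emax, divide by the oral slope, round to the nearest practical
  oral step, minimum one step). A configurable transition allowance
  (default 0) can deliberately undershoot. This reproduces the published
  moderate and fast haloperidol switch doses (1.5 and 0.5 mg/day); the
  published slow-class doses sit below what trough matching yields and
  appear to embed additional clinical judgement, so they are not treated as
  algorithm ground truth.
* **Step doses are continuous by default**: snapping the hyperbolic tail
  to tablet-size increments collapses the final steps to zero and produces
  an occupancy cliff, so practical rounding is opt-in (`step_grid_mg`),
  on the understanding that liquid/compounded preparations permit fine
  division. The switch dose itself still uses the practical increment.
* **Stop rule**: reductions proceed in exact class-rate decrements while
  the target occupancy stays positive; once occupancy is within one step of
  zero, a single final step to zero follows (final drop ≤ the class rate).

## Plan verification, and a structural caveat

`verify_plan` simulates the complete plan — steady-state history of the
starting regimen, reduced depot, residual washout, constant oral phases —
and reports the largest 30-day occupancy decline (0.5-point tolerance for
rounding effects). Under this whole-trajectory check the generated plans
*exceed* their class limits at the transitions: after the oral switch the
residual depot (about a full trough-equivalent of drug) washes out on top
of the matched oral level, an inherent decline of roughly one swing-limit
that overlaps the first monthly steps (e.g. ~8.3 points against 5+0.5 for
the moderate haloperidol plan, peaking around day 129); the single-step
depot reduction shows the same effect for fast-class plans. This is a
property of the procedure itself, which constrains steady-state swings and
monthly step sizes but never the transition windows; the package surfaces
it rather than hiding it. Slower transitions (longer holds, staged oral
entry) would be needed to make the whole trajectory compliant.

## What the validation shows — and does not

The validation suite recomputes published quantities from the shipped
constants: occupancy arithmetic and unit conversions are exact to printed
precision; swings recomputed from published concentration pairs agree to
0.02 points; the abrupt-discontinuation peak decline for zuclopenthixol
matches to 0.07 points; 2-weekly steady-state concentrations to ~2%.
Failures are retained where the reconstruction genuinely cannot reach the
published numbers (3-/4-weekly concentrations and the threshold cells
depending on them; whole-trajectory plan compliance). All of this validates
internal consistency against published model outputs — not clinical
accuracy: the inputs are population means, and six-fold between-patient
half-life variation is documented for these esters.
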