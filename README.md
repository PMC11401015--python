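# lidataper

Pharmacokinetic/pharmacodynamic simulation and hyperbolic taper design for
decanoate-based long-acting injectable dopamine antagonists (LIDAs —
"antipsychotic depots"): flupentixol, zuclopenthixol and haloperidol
decanoate.

Stopping dopamine antagonists abruptly risks withdrawal symptoms and
relapse; deprescribing guidance increasingly favours *hyperbolic* tapering,
in which each dose reduction lowers striatal D2 receptor occupancy by an
equal number of percentage points. Because occupancy saturates with plasma
level, equal occupancy decrements require hyperbolically shrinking doses.
`lidataper` is for clinical pharmacologists and deprescribing researchers
who want to simulate depot regimens, quantify how fast occupancy changes,
and design constraint-compatible reduction schedules down to full
discontinuation.

## Model

Each injection contributes a dose-proportional single-dose profile and
doses superpose:

```
C(t) = Σᵢ p · Dᵢ · g(t − tᵢ)
```

where `g` is a unit response normalised to 1 at the single-dose peak
(`g(tmax) = 1`), with terminal decay `exp(−ke·t)`, `ke = ln2 / t½`, and `p`
(peak ng/ml per mg) is calibrated so the steady-state peak of a published
anchor regimen matches its published Css,max. Two shapes are available:
a linear rise to the peak followed by exponential decay (default), and a
first-order-absorption bi-exponential whose absorption rate solves
`tmax = ln(ka/ke)/(ka − ke)`. For periodic dosing the steady state has an
exact geometric-series closed form.

Plasma level maps to occupancy through the Emax (Michaelis–Menten) model

```
Occ(%) = Emax · C / (C + EC50),       Emax = 100%
```

and the rate of D2 occupancy change (RODOC) is measured either as the
steady-state peak-to-trough occupancy swing within one inter-dose interval,
or — after abrupt discontinuation — as the largest occupancy decline over
any 30-day window of the residual tail. Taper-rate classes cap the change
at 1.25 / 2.5 / 5 / 10 percentage points (very slow / slow / moderate /
fast). Daily oral dosing is a constant level `slope · dose` (linear
dose–concentration relation).

A taper plan reduces the depot in one step to the lowest class-compatible
2-weekly dose (the *threshold dose*, found by bisection on the descending
branch of the swing-vs-dose curve and rounded up to the 0.2-ml ampoule
grid), holds ~3 months, switches to a daily oral dose matching the depot
trough occupancy, holds 2 months, then reduces monthly in equal occupancy
decrements to zero. Plans are verified by simulating the whole trajectory
— residual depot included — against the class limit on every 30-day window.

## Worked example

```python
from lidataper import (default_drug_params, steady_state_summary,
                       abrupt_discontinuation_profile, peak_window_drop)

flu = default_drug_params("flupentixol")
s = steady_state_summary(200, 14, flu)
print(round(s.cmin_ng_ml, 2), round(s.cmax_ng_ml, 2), round(s.swing_points, 2))
# 22.02 29.29 0.73

zuc = default_drug_params("zuclopenthixol")
occ = abrupt_discontinuation_profile(600, 7, zuc, horizon_days=400)
print(round(peak_window_drop(occ, 30), 2))
# 26.7
```

The first line: on 200 mg flupentixol decanoate every 2 weeks, plasma level
oscillates between ~22 and ~29 ng/ml at steady state, and occupancy moves
only 0.73 points per interval — far inside even the very-slow limit. The
second: abruptly stopping 600 mg weekly zuclopenthixol produces a peak
occupancy decline of 26.7 points per 30 days, nearly triple the fastest
acceptable taper rate, which is why depot discontinuation still needs a
staged taper and an oral switch.

Longer narrative walk-throughs live in `examples/` (steady-state tables,
abrupt discontinuation, threshold doses, full taper plans), and a thin CLI
wraps the same functions:

```
lidataper thresholds --drug haloperidol --rate moderate
lidataper plan --drug haloperidol --dose 300 --interval-days 28 --rate moderate --out out/
lidataper tables --out out/tables
```

`lidataper tables` regenerates the steady-state, occupancy and threshold
tables from the shipped drug constants and writes diff columns against the
published reference values embedded in `lidataper.reference`.

## Caveats

The exact single-dose equations behind the published steady-state
concentration tables are not recoverable from the published text; the
reconstructed profiles reproduce the 2-weekly steady-state values to ~2%
but deviate at 3- and 4-weekly intervals (see `docs/methods.md` for the
analysis and its consequences for threshold doses). All outputs are
population-average, single-compartment predictions with no between-patient
variability — design aids, not individual dosing advice.
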