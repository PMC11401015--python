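"""Minimum depot doses compatible with each taper-rate class.

Below these doses the steady-state occupancy swing within one inter-dose
interval exceeds the class limit, so the taper must continue in oral form.
"""

from lidataper import RATE_CLASSES, default_drug_params, threshold_dose

for drug in ("flupentixol", "haloperidol", "zuclopenthixol"):
    params = default_drug_params(drug)
    print(f"{drug} — lowest compliant depot dose (mg), rounded to the ampoule grid")
    header = "  ".join(f"{c.name:>10s}" for c in RATE_CLASSES)
    print(f"{'interval':>10s}  {header}")
    for interval in (14.0, 21.0, 28.0):
        cells = []
        for cls in RATE_CLASSES:
            thr = threshold_dose(params, interval, cls)
            if not thr.feasible:
                cells.append(f"{'n/a':>10s}")
            elif not thr.binding:
                cells.append(f"{thr.rounded_dose_mg:>8g}mg*")
            else:
                cells.append(f"{thr.rounded_dose_mg:>9g}mg")
        print(f"{interval:>8g} d  " + "  ".join(cells))
    print()

print("'n/a': even the maximum licensed dose swings more than the class limit")
print("at that interval — tapering at that frequency is not possible within")
print("the constraint. '*': the limit never binds at that interval; the")
print("threshold collapses to the smallest practical dose. Classes limit the")
print("occupancy change per inter-dose interval to 1.25 (very_slow), 2.5")
print("(slow), 5 (moderate) and 10 (fast) percentage points.")
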