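"""Steady-state peaks, troughs and occupancy swing for depot regimens.

Simulates flupentixol decanoate at the same dose given less and less often.
The peak/trough ratio widens with the interval, so the occupancy swing per
interval grows even though the average drug delivered per week falls.
"""

from lidataper import default_drug_params, steady_state_summary

params = default_drug_params("flupentixol")

print("flupentixol decanoate — steady state (calibrated model)")
print(f"{'regimen':>18s} {'Cmin':>7s} {'Cmax':>7s} {'occ@Cmin':>9s} {'occ@Cmax':>9s} {'swing':>6s}")
for dose, interval in [(200, 14), (200, 21), (200, 28), (80, 14), (120, 21), (160, 28)]:
    s = steady_state_summary(dose, interval, params)
    print(f"{dose:>6g} mg / {interval:>3g} d "
          f"{s.cmin_ng_ml:7.2f} {s.cmax_ng_ml:7.2f} "
          f"{s.occ_at_cmin_percent:8.2f}% {s.occ_at_cmax_percent:8.2f}% "
          f"{s.swing_points:5.2f}")

print()
print("Concentrations are ng/ml; occupancies are striatal D2 percent from the")
print("Emax model. 'swing' is the occupancy change across one inter-dose")
print("interval — the quantity taper-rate constraints are applied to. Note the")
print("bottom three rows deliver the same 40 mg/week yet swing progressively")
print("more as the interval lengthens.")
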