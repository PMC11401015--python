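"""Published reference values for the three shipped depots.

These are the printed peak/trough levels, occupancies, threshold doses and
discontinuation rates from the pharmacokinetic/neuroimaging modelling
literature that the shipped drug defaults derive from. They power the diff
reports (``lidataper tables``) and the validation suite; they are inputs for
comparison, never part of the computation itself.
"""

from __future__ import annotations

# Maximum licensed regimen: (dose_mg, interval_days, css_max_ng_ml, occ_at_cmax_pct)
TABLE1_MAX_LICENSED = {
    "flupentixol": (400.0, 7.0, 102.61, 99.34),
    "haloperidol": (300.0, 28.0, 9.65, 94.98),
    "zuclopenthixol": (600.0, 7.0, 45.73, 97.53),
}

# Unit-conversion anchors: (value_nmol_per_l, molar_mass_g_mol, ng_per_ml)
CONVERSION_ANCHORS = (
    (2.887, 400.965, 1.158),   # zuclopenthixol EC50
    (28.22, 375.9, 10.61),     # haloperidol 10 mg oral level
)

# Flupentixol steady-state regimens:
# (dose_mg, interval_days, cmin, occ_at_cmin, cmax, occ_at_cmax, swing_points)
TABLE2_FLUPENTIXOL = (
    # (a) same dose, varying frequency
    (200.0, 14.0, 21.62, 96.95, 29.69, 97.76, 0.81),
    (200.0, 21.0, 10.48, 93.91, 18.55, 96.46, 2.56),
    (200.0, 28.0, 5.96, 89.75, 14.03, 95.38, 5.63),
    # (b) equal per-weekly dose, varying frequency
    (80.0, 14.0, 8.65, 92.71, 11.87, 94.58, 1.87),
    (120.0, 21.0, 6.29, 90.24, 11.13, 94.24, 4.00),
    (160.0, 28.0, 4.77, 87.51, 11.22, 94.29, 6.78),
)

# Threshold depot doses (mg) by class and interval; None = not possible below
# the licensed maximum at that interval
TABLE3_THRESHOLDS = {
    "flupentixol": {
        "slow": {14.0: 60.0, 21.0: 220.0, 28.0: None},
        "moderate": {14.0: 24.0, 21.0: 100.0, 28.0: 240.0},
        "fast": {14.0: 8.0, 21.0: 36.0, 28.0: 100.0},
    },
    "haloperidol": {
        "slow": {14.0: 90.0, 21.0: None, 28.0: None},
        "moderate": {14.0: 40.0, 21.0: 180.0, 28.0: None},
        "fast": {14.0: 10.0, 21.0: 70.0, 28.0: 200.0},
    },
    "zuclopenthixol": {
        "slow": {14.0: 200.0, 21.0: None, 28.0: None},
        "moderate": {14.0: 80.0, 21.0: 400.0, 28.0: None},
        "fast": {14.0: 40.0, 21.0: 160.0, 28.0: 400.0},
    },
}

# Recommended starting oral doses (mg/day) at each class's 2-weekly threshold
TABLE4_ORAL_SWITCH = {
    "flupentixol": {"slow": 13.0, "moderate": 7.5, "fast": 3.0},
    "haloperidol": {"slow": 2.0, "moderate": 1.5, "fast": 0.5},
    "zuclopenthixol": {"slow": 8.0, "moderate": 5.0, "fast": 2.0},
}

# Peak rate of occupancy decline after abrupt discontinuation of the maximum
# licensed regimen (percentage points per 30 days)
PEAK_RODOC = {
    "flupentixol": 27.47,
    "zuclopenthixol": 26.63,
    "haloperidol": 24.86,
}
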