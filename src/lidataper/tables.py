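"""Regenerate the summary tables from the shipped defaults, with diffs
against the published reference values."""

from __future__ import annotations

import pandas as pd

from . import reference
from .occupancy import occupancy_from_concentration
from .params import DrugParams, default_drug_params
from .pk import DEFAULT_PROFILE_MODEL, ProfileModel, steady_state_summary
from .design import threshold_dose
from .rodoc import RATE_CLASSES, rate_class, swing_from_concentrations


def max_licensed_table(profile_model: ProfileModel = DEFAULT_PROFILE_MODEL) -> pd.DataFrame:
    """Maximum licensed regimens: anchor Css,max and its Emax occupancy."""
    rows = []
    for drug, (dose, interval, cmax_ref, occ_ref) in reference.TABLE1_MAX_LICENSED.items():
        params = default_drug_params(drug)
        occ = occupancy_from_concentration(cmax_ref, params.emax_percent, params.ec50_ng_ml)
        rows.append({
            "drug": drug,
            "half_life_days": params.half_life_days,
            "tmax_days": params.tmax_days,
            "max_dose_mg": dose,
            "interval_days": interval,
            "css_max_ng_ml": cmax_ref,
            "occ_at_cmax_percent": round(occ, 2),
            "occ_reference": occ_ref,
            "occ_diff": round(occ - occ_ref, 4),
        })
    return pd.DataFrame(rows)


def steady_state_table(drug: str = "flupentixol",
                       profile_model: ProfileModel = DEFAULT_PROFILE_MODEL) -> pd.DataFrame:
    """Simulated steady-state peaks/troughs for the reference regimens,
    against the printed concentrations and the occupancy arithmetic."""
    params = default_drug_params(drug)
    rows = []
    for dose, interval, cmin_ref, occ_min_ref, cmax_ref, occ_max_ref, swing_ref \
            in reference.TABLE2_FLUPENTIXOL:
        s = steady_state_summary(dose, interval, params, profile_model)
        swing_printed = swing_from_concentrations(cmax_ref, cmin_ref, params)
        rows.append({
            "dose_mg": dose,
            "interval_days": interval,
            "cmin_sim": round(s.cmin_ng_ml, 2),
            "cmin_ref": cmin_ref,
            "cmin_rel_err": round(s.cmin_ng_ml / cmin_ref - 1, 4),
            "cmax_sim": round(s.cmax_ng_ml, 2),
            "cmax_ref": cmax_ref,
            "cmax_rel_err": round(s.cmax_ng_ml / cmax_ref - 1, 4),
            "swing_sim": round(s.swing_points, 2),
            "swing_from_ref_conc": round(swing_printed, 4),
            "swing_ref": swing_ref,
        })
    return pd.DataFrame(rows)


def threshold_table(profile_model: ProfileModel = DEFAULT_PROFILE_MODEL,
                    include_very_slow: bool = True) -> pd.DataFrame:
    """Threshold depot doses per drug, interval and rate class, with the
    published doses and the distance in formulation increments."""
    rows = []
    classes = [c for c in RATE_CLASSES if include_very_slow or c.name != "very_slow"]
    for drug in reference.TABLE3_THRESHOLDS:
        params = default_drug_params(drug)
        for cls in classes:
            ref_by_interval = reference.TABLE3_THRESHOLDS[drug].get(cls.name, {})
            for interval in (14.0, 21.0, 28.0):
                thr = threshold_dose(params, interval, cls, profile_model)
                ref_dose = ref_by_interval.get(interval, float("nan"))
                row = {
                    "drug": drug,
                    "rate_class": cls.name,
                    "interval_days": interval,
                    "raw_dose_mg": None if thr.raw_dose_mg is None else round(thr.raw_dose_mg, 1),
                    "rounded_dose_mg": thr.rounded_dose_mg,
                    "feasible": thr.feasible,
                    "reference_dose_mg": ref_dose,
                }
                if thr.feasible and ref_dose is not None and ref_dose == ref_dose:
                    inc = _increment_at(params, max(thr.rounded_dose_mg, ref_dose))
                    row["increments_off"] = round(
                        abs(thr.rounded_dose_mg - ref_dose) / inc, 2)
                rows.append(row)
    return pd.DataFrame(rows)


def _increment_at(params: DrugParams, dose: float) -> float:
    for band in params.depot_increments:
        if dose <= band.upper_dose_mg:
            return band.increment_mg
    return params.depot_increments[-1].increment_mg
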