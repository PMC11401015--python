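"""Per-drug pharmacological constants, unit conversions and the oral dose map.

Every quantity the simulation needs for one drug lives in a frozen
:class:`DrugParams`: depot pharmacokinetics (apparent elimination half-life,
time to single-dose peak), the Emax/EC50 occupancy relationship, a published
steady-state peak used to calibrate the depot concentration scale, the linear
oral dose->plasma-level slope, and the practical dosing grids (depot ampoule
increments, smallest oral step). Defaults for flupentixol, zuclopenthixol and
haloperidol decanoate ship in ``data/drugs.default.yaml``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "DepotAnchor",
    "IncrementBand",
    "MaxLicensed",
    "DrugParams",
    "convert_nmol_per_l_to_ng_per_ml",
    "oral_level",
    "load_drug_params",
    "default_drug_params",
    "available_drugs",
    "dump_drug_params",
]


def _require_finite_positive(name: str, value: float, strict: bool = True) -> None:
    if not math.isfinite(value) or (value <= 0 if strict else value < 0):
        kind = "positive" if strict else "non-negative"
        raise ValueError(f"{name} must be a finite {kind} number, got {value!r}")


@dataclass(frozen=True)
class DepotAnchor:
    """A published steady-state peak that pins the depot concentration scale."""

    dose_mg: float
    interval_days: float
    css_max_ng_ml: float

    def __post_init__(self) -> None:
        _require_finite_positive("anchor dose_mg", self.dose_mg)
        _require_finite_positive("anchor interval_days", self.interval_days)
        _require_finite_positive("anchor css_max_ng_ml", self.css_max_ng_ml)


@dataclass(frozen=True)
class IncrementBand:
    """Dosing grid band: doses up to ``upper_dose_mg`` round in ``increment_mg`` steps."""

    upper_dose_mg: float
    increment_mg: float

    def __post_init__(self) -> None:
        _require_finite_positive("increment_mg", self.increment_mg)
        if not self.upper_dose_mg > 0:  # inf allowed
            raise ValueError("upper_dose_mg must be positive")


@dataclass(frozen=True)
class MaxLicensed:
    dose_mg: float
    interval_days: float

    def __post_init__(self) -> None:
        _require_finite_positive("max licensed dose_mg", self.dose_mg)
        _require_finite_positive("max licensed interval_days", self.interval_days)


@dataclass(frozen=True)
class DrugParams:
    """All pharmacological constants for one depot drug.

    Parameters
    ----------
    half_life_days
        Apparent elimination half-life of the depot (terminal log-linear
        decay rate is ln2 / half_life_days).
    tmax_days
        Time from a single injection to its plasma peak.
    emax_percent, ec50_ng_ml
        Emax-model occupancy parameters (occupancy = Emax*C/(C+EC50)).
    depot_anchor
        Steady-state peak used by the calibration step (see ``lidataper.pk``).
    oral_slope_ng_ml_per_mg
        Plasma level per mg of daily oral dose; the oral map is linear with
        no intercept.
    depot_increments
        Ordered bands of the practical depot dosing grid; at exactly a band
        boundary the lower band's increment applies.
    oral_increment_mg
        Smallest practical oral step, used for the oral switch dose.
    """

    name: str
    half_life_days: float
    tmax_days: float
    emax_percent: float
    ec50_ng_ml: float
    molar_mass_g_mol: float
    depot_anchor: DepotAnchor | None
    oral_slope_ng_ml_per_mg: float
    depot_increments: tuple[IncrementBand, ...]
    oral_increment_mg: float
    max_licensed: MaxLicensed
    oral_slope_alternatives: tuple[tuple[str, float], ...] = field(default=())

    def __post_init__(self) -> None:
        _require_finite_positive("half_life_days", self.half_life_days)
        _require_finite_positive("tmax_days", self.tmax_days)
        if not 0 < self.emax_percent <= 100:
            raise ValueError("emax_percent must lie in (0, 100]")
        _require_finite_positive("ec50_ng_ml", self.ec50_ng_ml)
        _require_finite_positive("molar_mass_g_mol", self.molar_mass_g_mol)
        _require_finite_positive("oral_slope_ng_ml_per_mg", self.oral_slope_ng_ml_per_mg)
        _require_finite_positive("oral_increment_mg", self.oral_increment_mg)
        if not self.depot_increments:
            raise ValueError("depot_increments must contain at least one band")
        uppers = [b.upper_dose_mg for b in self.depot_increments]
        if sorted(uppers) != uppers:
            raise ValueError("depot_increments bands must be ordered by upper_dose_mg")
        if uppers[-1] < self.max_licensed.dose_mg:
            raise ValueError("depot_increments must cover up to the maximum licensed dose")

    @property
    def ke_per_day(self) -> float:
        """Terminal elimination rate constant (1/day)."""
        return math.log(2.0) / self.half_life_days


def convert_nmol_per_l_to_ng_per_ml(value: float, molar_mass: float) -> float:
    """Convert a molar plasma concentration (nmol/L) to ng/ml.

    nmol/L x g/mol = ng/L; dividing by 1000 gives ng/ml. E.g. 2.887 nmol/L of
    zuclopenthixol (400.965 g/mol) is 1.158 ng/ml.
    """
    if not math.isfinite(value) or value < 0:
        raise ValueError(f"concentration must be finite and non-negative, got {value!r}")
    _require_finite_positive("molar_mass", molar_mass)
    return value * molar_mass / 1000.0


def oral_level(dose_mg: float, params: DrugParams) -> float:
    """Plasma level (ng/ml) produced by a daily oral dose, linear with no intercept."""
    if not math.isfinite(dose_mg) or dose_mg < 0:
        raise ValueError(f"oral dose must be finite and non-negative, got {dose_mg!r}")
    return params.oral_slope_ng_ml_per_mg * dose_mg


# ---------------------------------------------------------------------------
# configuration I/O

def _params_from_mapping(name: str, doc: Mapping) -> DrugParams:
    try:
        anchor = DepotAnchor(**doc["depot_anchor"])
        bands = tuple(IncrementBand(**b) for b in doc["depot_increments"])
        maxlic = MaxLicensed(**doc["max_licensed"])
        alternatives = tuple(sorted((doc.get("oral_slope_alternatives") or {}).items()))
        return DrugParams(
            name=name,
            half_life_days=float(doc["half_life_days"]),
            tmax_days=float(doc["tmax_days"]),
            emax_percent=float(doc["emax_percent"]),
            ec50_ng_ml=float(doc["ec50_ng_ml"]),
            molar_mass_g_mol=float(doc["molar_mass_g_mol"]),
            depot_anchor=anchor,
            oral_slope_ng_ml_per_mg=float(doc["oral_slope_ng_ml_per_mg"]),
            depot_increments=bands,
            oral_increment_mg=float(doc["oral_increment_mg"]),
            max_licensed=maxlic,
            oral_slope_alternatives=alternatives,
        )
    except KeyError as exc:  # pragma: no cover - config authoring error
        raise ValueError(f"drug config for {name!r} is missing key {exc}") from exc


def _params_to_mapping(params: DrugParams) -> dict:
    doc = asdict(params)
    doc.pop("name")
    doc["oral_slope_alternatives"] = dict(params.oral_slope_alternatives)
    if not doc["oral_slope_alternatives"]:
        doc.pop("oral_slope_alternatives")
    return doc


def load_drug_params(path: str | Path) -> dict[str, DrugParams]:
    """Load a multi-drug YAML config (one document, one mapping per drug)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return {name: _params_from_mapping(name, doc) for name, doc in raw.items()}


def dump_drug_params(drugs: Mapping[str, DrugParams], path: str | Path) -> None:
    """Serialize drug parameters back to the YAML config layout."""
    doc = {name: _params_to_mapping(p) for name, p in drugs.items()}
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _default_config() -> dict[str, DrugParams]:
    ref = resources.files("lidataper").joinpath("data/drugs.default.yaml")
    raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return {name: _params_from_mapping(name, doc) for name, doc in raw.items()}


def available_drugs() -> tuple[str, ...]:
    """Names of the drugs shipped in the default configuration."""
    return tuple(_default_config())


def default_drug_params(name: str) -> DrugParams:
    """Shipped defaults for ``flupentixol``, ``haloperidol`` or ``zuclopenthixol``."""
    cfg = _default_config()
    try:
        return cfg[name]
    except KeyError:
        raise KeyError(f"unknown drug {name!r}; shipped drugs: {sorted(cfg)}") from None
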