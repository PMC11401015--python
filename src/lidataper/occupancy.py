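"""Emax (Michaelis-Menten) mapping between plasma level and D2 occupancy.

Occupancy(%) = Emax * PC / (PC + EC50), where PC is the plasma concentration
in ng/ml and EC50 the level giving half-maximal occupancy. The transform is
strictly increasing and concave, saturating below Emax; its algebraic inverse
PC = EC50 * occ / (Emax - occ) is needed when a taper step is specified as an
occupancy target and the corresponding dose must be recovered.
"""

from __future__ import annotations

import math

import numpy as np

from .params import DrugParams
from .profiles import ConcentrationProfile, OccupancyProfile

__all__ = [
    "occupancy_from_concentration",
    "concentration_from_occupancy",
    "occupancy_profile",
]


def occupancy_from_concentration(pc, emax: float = 100.0, ec50: float = 1.0):
    """Receptor occupancy (percent) at plasma concentration ``pc`` (ng/ml).

    Accepts scalars or arrays; scalar input returns a float.
    """
    pc_arr = np.asarray(pc, dtype=float)
    if np.any(pc_arr < 0) or not np.all(np.isfinite(pc_arr)):
        raise ValueError("plasma concentration must be finite and non-negative")
    if ec50 <= 0:
        raise ValueError("ec50 must be positive")
    out = emax * pc_arr / (pc_arr + ec50)
    return float(out) if np.isscalar(pc) or pc_arr.ndim == 0 else out


def concentration_from_occupancy(occ: float, emax: float = 100.0, ec50: float = 1.0) -> float:
    """Plasma concentration (ng/ml) producing occupancy ``occ`` percent.

    Exact inverse of :func:`occupancy_from_concentration`; occupancies at or
    above Emax are unreachable at any finite concentration.
    """
    if not math.isfinite(occ) or occ < 0:
        raise ValueError("occupancy must be finite and non-negative")
    if occ >= emax:
        raise ValueError(f"occupancy {occ} is unreachable (Emax = {emax})")
    return ec50 * occ / (emax - occ)


def occupancy_profile(profile: ConcentrationProfile, params: DrugParams) -> OccupancyProfile:
    """Pointwise Emax transform of a concentration trajectory."""
    values = occupancy_from_concentration(
        profile.values, params.emax_percent, params.ec50_ng_ml
    )
    return OccupancyProfile(profile.start_day, profile.step_days, values)
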