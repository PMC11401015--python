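"""Uniform time-grid trajectory containers (plasma level and occupancy)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ConcentrationProfile", "OccupancyProfile"]


@dataclass(frozen=True)
class _GridProfile:
    start_day: float
    step_days: float
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.step_days <= 0:
            raise ValueError("step_days must be positive")
        if values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if np.any(values < -1e-9):
            raise ValueError("profile values must be non-negative")

    @property
    def times(self) -> np.ndarray:
        return self.start_day + self.step_days * np.arange(len(self.values))

    def __len__(self) -> int:
        return len(self.values)

    def at(self, day: float) -> float:
        """Linear interpolation at an arbitrary day within the grid."""
        return float(np.interp(day, self.times, self.values))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"day": self.times, self._column: self.values})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")


@dataclass(frozen=True)
class ConcentrationProfile(_GridProfile):
    """Plasma concentration (ng/ml) on a uniform day grid."""

    _column = "concentration_ng_ml"


@dataclass(frozen=True)
class OccupancyProfile(_GridProfile):
    """D2 receptor occupancy (percent) on a uniform day grid."""

    _column = "occupancy_percent"
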