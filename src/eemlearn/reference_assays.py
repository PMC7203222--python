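"""Closed-form reference assays used to build response tables.

Currently: the modified Arnaud equation for chlorophyll-a in methanol
extracts,

    Chla (mg/L) = (16.72 * A665 - 9.16 * A652) * dilution_factor,

from absorbances at 665 and 652 nm.  A negative result is physically a bad
extract; it is returned as-is with a warning rather than clamped, so assay
failures stay visible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ChlorophyllReading", "arnaud_chlorophyll", "batch_chlorophyll"]

A665_COEF = 16.72
A652_COEF = 9.16


@dataclass(frozen=True)
class ChlorophyllReading:
    a665: float
    a652: float
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("a665", "a652", "dilution_factor"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.dilution_factor <= 0:
            raise ValueError(f"dilution_factor must be > 0, got {self.dilution_factor}")


def arnaud_chlorophyll(
    reading: ChlorophyllReading | float,
    a652: float | None = None,
    dilution_factor: float = 1.0,
) -> float:
    """Chlorophyll-a concentration in mg/L from a spectrophotometric reading.

    Accepts either a :class:`ChlorophyllReading` or the raw
    ``(a665, a652, dilution_factor)`` values.
    """
    if not isinstance(reading, ChlorophyllReading):
        reading = ChlorophyllReading(float(reading), float(a652), float(dilution_factor))
    chla = (A665_COEF * reading.a665 - A652_COEF * reading.a652) * reading.dilution_factor
    if chla < 0:
        warnings.warn(
            f"negative chlorophyll ({chla:.4g} mg/L): extract likely degraded",
            stacklevel=2,
        )
    return chla


def batch_chlorophyll(in_path: str | Path, out_path: str | Path) -> pd.DataFrame:
    """Batch mode: CSV (sample_id, a665, a652, dilution) -> CSV with mg/L column."""
    df = pd.read_csv(in_path)
    required = {"sample_id", "a665", "a652"}
    if not required.issubset(df.columns):
        raise ValueError(f"{in_path}: needs columns {sorted(required)}")
    dilution = df["dilution"] if "dilution" in df.columns else 1.0
    df = df.copy()
    df["chlorophyll_mg_per_L"] = (A665_COEF * df["a665"] - A652_COEF * df["a652"]) * dilution
    df.to_csv(out_path, index=False)
    return df
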