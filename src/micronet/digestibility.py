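"""Apparent total-tract digestibility (ATTD) from the acid-insoluble-ash
(AIA) intrinsic marker.

ATTD(%) = (1 - (Ad * Nf) / (Af * Nd)) * 100

where Ad/Af are the marker concentrations (g/kg) in diet and feces and
Nd/Nf the nutrient concentrations (g/kg) in diet and feces. Negative values
are possible under marker measurement error; they are returned unclamped
and flagged in logs so data problems stay visible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ATTDRecord:
    Ad: float        # marker in diet, g/kg
    Af: float        # marker in feces, g/kg
    Nd: float        # nutrient in diet, g/kg
    Nf: float        # nutrient in feces, g/kg
    nutrient: str = "OM"   # e.g. OM, NDF, ADF, EE, CP

    def __post_init__(self) -> None:
        if self.Ad <= 0 or self.Af <= 0 or self.Nd <= 0:
            raise ValueError("Ad, Af and Nd must be positive")
        if self.Nf < 0:
            raise ValueError("Nf must be non-negative")


def attd(rec: ATTDRecord) -> float:
    """Apparent total-tract digestibility in percent (at most 100)."""
    value = (1.0 - (rec.Ad * rec.Nf) / (rec.Af * rec.Nd)) * 100.0
    if value < 0:
        logger.warning("negative ATTD (%.2f%%) for %s: check marker recovery",
                       value, rec.nutrient)
    return value


def attd_table(records: pd.DataFrame) -> pd.DataFrame:
    """Vectorized ATTD over a records table with columns Ad, Af, Nd, Nf
    (and optionally ``nutrient``); returns the table with an ``attd_percent``
    column appended."""
    required = {"Ad", "Af", "Nd", "Nf"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = records.copy()
    out["attd_percent"] = [
        attd(ATTDRecord(r.Ad, r.Af, r.Nd, r.Nf,
                        getattr(r, "nutrient", "OM")))
        for r in records.itertuples()
    ]
    return out
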