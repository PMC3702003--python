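"""Drinking-water equivalent levels (DWELs).

A DWEL is the tap-water concentration at which a consumer ingesting water at a
given per-body-weight rate receives exactly the fraction of the acceptable
daily intake allocated to drinking water:

    DWEL (ng/L) = dose (µg/kg/day) × RSC × 10^6 / rate (mL/kg/day)

The 10^6 combines the µg→ng (×1000) and mL→L (×1000) unit conversions; body
weight cancels because both dose and ingestion rate are per kg.  DWELs are
inversely proportional to the ingestion rate, so the most protective (lowest)
DWEL belongs to the life stage that drinks the most water per kg — the first
months of life.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import NotAssessableError, ValidationError
from .exposure_factors import ExposureFactorTable
from .toxicity import CompoundRecord

__all__ = ["compute_dwel", "DWELProfile", "dwel_profile", "round_sig"]

_UNIT_FACTOR = 1.0e6  # (µg -> ng) x (mL -> L)


def compute_dwel(dose: float, rsc: float, rate_per_kg: float) -> float:
    """Convert a dose (µg/kg/day) into a DWEL (ng/L) at one ingestion rate.

    ``rsc`` is the relative source contribution from drinking water, a
    fraction in (0, 1]; ``rate_per_kg`` is in mL/kg/day.
    """
    for name, x in (("dose", dose), ("rsc", rsc), ("rate_per_kg", rate_per_kg)):
        if not (x > 0) or not math.isfinite(x):
            raise ValidationError(f"{name} must be positive and finite, got {x}")
    if rsc > 1:
        raise ValidationError(f"rsc must be <= 1, got {rsc}")
    return dose * rsc * _UNIT_FACTOR / rate_per_kg


@dataclass(frozen=True)
class DWELProfile:
    """Age-dependent DWELs for one compound (ng/L, full floating precision)."""

    compound: str
    rsc_used: float
    per_interval: dict  # interval label -> DWEL ng/L, in age order

    @property
    def values(self) -> np.ndarray:
        return np.array(list(self.per_interval.values()))

    @property
    def labels(self) -> list[str]:
        return list(self.per_interval.keys())

    def min(self) -> float:
        return float(self.values.min())

    def max(self) -> float:
        return float(self.values.max())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compound": self.compound,
                "interval": self.labels,
                "dwel_ng_L": self.values,
                "rsc_used": self.rsc_used,
            }
        )


def dwel_profile(
    record: CompoundRecord,
    table: ExposureFactorTable,
    rsc_override: Optional[float] = None,
) -> DWELProfile:
    """Build the age-dependent DWEL profile for a compound.

    Selects the most restrictive toxicity basis of ``record`` and applies
    :func:`compute_dwel` at every interval of ``table``.  ``rsc_override``
    replaces the record's relative source contribution for sensitivity
    scenarios.
    """
    if not record.assessable:
        raise NotAssessableError(
            f"{record.compound}: no toxicity basis; cannot derive DWELs"
        )
    rsc = record.rsc if rsc_override is None else rsc_override
    dose = record.selected_basis().derived_dose
    per_interval = {
        iv.label: compute_dwel(dose, rsc, iv.ingestion_rate_per_kg) for iv in table
    }
    return DWELProfile(compound=record.compound, rsc_used=rsc, per_interval=per_interval)


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (report-time display convention)."""
    if x == 0:
        return 0.0
    return float(f"{x:.{sig}g}")
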