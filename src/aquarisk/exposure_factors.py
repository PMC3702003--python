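"""Life-stage exposure factors: age intervals and drinking-water ingestion rates.

The screening assessment divides the lifespan from birth to 70 years into 12
age intervals and attaches to each the 95th-percentile consumers-only
community-water ingestion rate expressed per kilogram of body weight
(mL/kg/day, U.S. EPA Exposure Factors Handbook convention).  Storing the rate
in per-body-weight form lets the DWEL formula collapse ingestion rate and body
weight into a single quantity, since only their ratio enters the conversion.

Intervals are half-open ``[age_start, age_end)`` in years; fractional ages are
allowed.  The bundled default table ships as a package data file with
provenance recorded in its header comments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterator, Union

import numpy as np
import pandas as pd

from .errors import DomainError, ParseError, ValidationError

__all__ = [
    "AgeInterval",
    "ExposureFactorTable",
    "load_exposure_factors",
    "interval_for_age",
    "DEFAULT_FIXTURE_ID",
]

DEFAULT_FIXTURE_ID = "default"

_REQUIRED_COLUMNS = (
    "label",
    "age_start_years",
    "age_end_years",
    "ingestion_rate_mL_per_kg_day",
)

#: tolerance (years) when checking that consecutive intervals are contiguous
_GAP_TOL = 1e-6


@dataclass(frozen=True)
class AgeInterval:
    """One life stage with its per-body-weight water ingestion rate.

    Parameters
    ----------
    label : str
        Human-readable stage name, e.g. ``"birth to <1 month"``.
    age_start, age_end : float
        Bounds in years; the interval is ``[age_start, age_end)``.
    ingestion_rate_per_kg : float
        95th-percentile drinking-water ingestion, mL per kg body weight per day.
    """

    label: str
    age_start: float
    age_end: float
    ingestion_rate_per_kg: float

    def __post_init__(self) -> None:
        if not self.label:
            raise ValidationError("age interval needs a non-empty label")
        if not (self.age_start < self.age_end):
            raise ValidationError(
                f"interval {self.label!r}: age_start ({self.age_start}) must be "
                f"< age_end ({self.age_end})"
            )
        if self.age_start < 0:
            raise ValidationError(f"interval {self.label!r}: negative age_start")
        if not (self.ingestion_rate_per_kg > 0) or not math.isfinite(
            self.ingestion_rate_per_kg
        ):
            raise ValidationError(
                f"interval {self.label!r}: ingestion rate must be positive and finite"
            )

    def contains(self, age: float) -> bool:
        return self.age_start <= age < self.age_end


class ExposureFactorTable:
    """Ordered, contiguous collection of :class:`AgeInterval`.

    Construction validates ordering and rejects overlapping or gapped
    intervals.  The table behaves as a sequence of intervals and offers
    vectorised access to its rates.
    """

    def __init__(self, intervals, provenance: str = ""):
        intervals = tuple(intervals)
        if not intervals:
            raise ValidationError("exposure-factor table must contain >= 1 interval")
        for prev, cur in zip(intervals, intervals[1:]):
            if cur.age_start < prev.age_end - _GAP_TOL:
                raise ValidationError(
                    f"intervals {prev.label!r} and {cur.label!r} overlap "
                    f"({cur.age_start} < {prev.age_end})"
                )
            if cur.age_start > prev.age_end + _GAP_TOL:
                raise ValidationError(
                    f"gap between intervals {prev.label!r} (ends {prev.age_end}) "
                    f"and {cur.label!r} (starts {cur.age_start})"
                )
        self.intervals = intervals
        self.provenance = provenance

    # -- sequence protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[AgeInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> AgeInterval:
        return self.intervals[i]

    # -- accessors ---------------------------------------------------------
    @property
    def age_min(self) -> float:
        return self.intervals[0].age_start

    @property
    def age_max(self) -> float:
        return self.intervals[-1].age_end

    def labels(self) -> list[str]:
        return [iv.label for iv in self.intervals]

    def rates(self) -> np.ndarray:
        """Ingestion rates (mL/kg/day) in interval order."""
        return np.array([iv.ingestion_rate_per_kg for iv in self.intervals])

    def interval_for_age(self, age: float) -> AgeInterval:
        """Return the unique interval with ``age_start <= age < age_end``."""
        if not (self.age_min <= age < self.age_max):
            raise DomainError(
                f"age {age} outside table coverage [{self.age_min}, {self.age_max})"
            )
        starts = np.array([iv.age_start for iv in self.intervals])
        idx = int(np.searchsorted(starts, age, side="right")) - 1
        return self.intervals[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels(),
                "age_start_years": [iv.age_start for iv in self.intervals],
                "age_end_years": [iv.age_end for iv in self.intervals],
                "ingestion_rate_mL_per_kg_day": self.rates(),
            }
        )


def _table_from_frame(df: pd.DataFrame, provenance: str) -> ExposureFactorTable:
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"exposure-factor table missing columns: {missing}")
    intervals = []
    for i, row in df.iterrows():
        try:
            intervals.append(
                AgeInterval(
                    label=str(row["label"]),
                    age_start=float(row["age_start_years"]),
                    age_end=float(row["age_end_years"]),
                    ingestion_rate_per_kg=float(row["ingestion_rate_mL_per_kg_day"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(f"exposure-factor row {i} is malformed: {exc}") from exc
    intervals.sort(key=lambda iv: iv.age_start)
    return ExposureFactorTable(intervals, provenance=provenance)


def load_exposure_factors(
    source: Union[str, Path] = DEFAULT_FIXTURE_ID,
) -> ExposureFactorTable:
    """Load an exposure-factor table from a CSV file or a built-in fixture id.

    ``source="default"`` loads the packaged 12-interval table (EPA
    Exposure Factors Handbook style, consumers-only community water, 95th
    percentile per-kg rates).  Otherwise ``source`` is treated as a path to a
    delimiter-separated file with columns ``label, age_start_years,
    age_end_years, ingestion_rate_mL_per_kg_day`` (``#`` comments allowed).
    """
    if isinstance(source, str) and source == DEFAULT_FIXTURE_ID:
        ref = resources.files("aquarisk.data").joinpath(
            "exposure_factors_synthetic.csv"
        )
        with resources.as_file(ref) as path:
            df = pd.read_csv(path, comment="#")
            provenance = _header_comment(path)
        return _table_from_frame(df, provenance=provenance)
    path = Path(source)
    if not path.exists():
        raise ParseError(f"exposure-factor file not found: {path}")
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pandas raises many parser types
        raise ParseError(f"cannot parse exposure-factor file {path}: {exc}") from exc
    return _table_from_frame(df, provenance=_header_comment(path))


def _header_comment(path: Path) -> str:
    lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                lines.append(line.lstrip("# ").rstrip())
            else:
                break
    return " ".join(lines)


def interval_for_age(table: ExposureFactorTable, age: float) -> AgeInterval:
    """Module-level alias of :meth:`ExposureFactorTable.interval_for_age`."""
    return table.interval_for_age(age)
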