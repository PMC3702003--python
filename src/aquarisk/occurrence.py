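"""Monitoring-campaign ingestion and occurrence statistics.

A campaign is a flat table of measurements: one row per (city, season,
sample, compound).  Concentrations below the limit of quantification (LOQ)
are left-censored and recorded as ``ND``.  Summary statistics follow the
screening conventions:

* detection frequency — detected rows / all rows for a compound;
* per-compound median and maximum are computed over *detected* values only
  (medians over all rows would be meaningless for compounds detected in well
  under half the samples); an LOQ/2 substitution mode is available for
  sensitivity analysis;
* percent of samples positive — samples containing >= 1 detected compound /
  distinct samples, where a sample is identified by (city, season, sample_id);
* detection index — total detections across compounds per sample within a
  city (optionally a season); an index >= 3 flags a contamination hot spot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import DomainError, ParseError, ValidationError

__all__ = [
    "SEASONS",
    "HOT_SPOT_INDEX",
    "Measurement",
    "read_campaign",
    "write_campaign",
    "measurements_to_frame",
    "detection_frequency",
    "percent_samples_positive",
    "percent_detections_below",
    "detection_index",
    "compound_summary",
    "compound_maxima",
    "seasonal_comparison",
    "campaign_summary",
    "CampaignSummary",
]

SEASONS = ("dry", "wet")
HOT_SPOT_INDEX = 3.0
ND = "ND"


@dataclass(frozen=True)
class Measurement:
    """One concentration observation; ``value`` is ``None`` when censored."""

    city: str
    season: str
    sample_id: str
    compound: str
    value: Optional[float]  # ng/L, None = below LOQ (censored)
    loq: float  # ng/L

    def __post_init__(self) -> None:
        if self.season not in SEASONS:
            raise ValidationError(
                f"unknown season {self.season!r}; expected one of {SEASONS}"
            )
        if self.loq < 0 or not math.isfinite(self.loq):
            raise ValidationError(f"LOQ must be >= 0 and finite, got {self.loq}")
        if self.value is not None:
            if not math.isfinite(self.value):
                raise ValidationError("detected value must be finite")
            if self.value < self.loq:
                raise ValidationError(
                    f"{self.city}/{self.sample_id}/{self.compound}: detected value "
                    f"{self.value} below its LOQ {self.loq}"
                )

    @property
    def detected(self) -> bool:
        return self.value is not None

    @property
    def sample_key(self) -> tuple:
        return (self.city, self.season, self.sample_id)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_CAMPAIGN_COLUMNS = ("city", "season", "sample_id", "compound", "value_ng_L", "loq_ng_L")


def read_campaign(source: Union[str, Path]) -> list[Measurement]:
    """Parse a campaign CSV into validated measurements.

    Columns: ``city, season, sample_id, compound, value_ng_L, loq_ng_L``;
    a ``value_ng_L`` of ``ND`` marks a left-censored observation.  Lines
    starting with ``#`` are treated as comments.
    """
    path = Path(source)
    if not path.exists():
        raise ParseError(f"campaign file not found: {path}")
    try:
        df = pd.read_csv(path, comment="#", dtype={"value_ng_L": str, "sample_id": str})
    except Exception as exc:
        raise ParseError(f"cannot parse campaign file {path}: {exc}") from exc
    missing = [c for c in _CAMPAIGN_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"campaign file missing columns: {missing}")
    out: list[Measurement] = []
    for i, row in df.iterrows():
        raw = str(row["value_ng_L"]).strip()
        if raw.upper() == ND:
            value: Optional[float] = None
        else:
            try:
                value = float(raw)
            except ValueError as exc:
                raise ParseError(
                    f"campaign row {i}: value {raw!r} is neither numeric nor {ND!r}"
                ) from exc
        try:
            out.append(
                Measurement(
                    city=str(row["city"]),
                    season=str(row["season"]),
                    sample_id=str(row["sample_id"]),
                    compound=str(row["compound"]),
                    value=value,
                    loq=float(row["loq_ng_L"]),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"campaign row {i}: {exc}") from exc
    return out


def measurements_to_frame(measurements: Iterable[Measurement]) -> pd.DataFrame:
    rows = [
        {
            "city": m.city,
            "season": m.season,
            "sample_id": m.sample_id,
            "compound": m.compound,
            "value_ng_L": ND if m.value is None else m.value,
            "loq_ng_L": m.loq,
        }
        for m in measurements
    ]
    return pd.DataFrame(rows, columns=list(_CAMPAIGN_COLUMNS))


def write_campaign(
    measurements: Iterable[Measurement],
    path: Union[str, Path],
    header_comment: str = "",
) -> None:
    """Write measurements in the format accepted by :func:`read_campaign`."""
    df = measurements_to_frame(measurements)
    with open(path, "w") as fh:
        for line in header_comment.splitlines():
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def _of_compound(measurements: Iterable[Measurement], compound: str) -> list[Measurement]:
    ms = [m for m in measurements if m.compound == compound]
    if not ms:
        raise DomainError(f"no measurements of compound {compound!r}")
    return ms


def detection_frequency(measurements: Iterable[Measurement], compound: str) -> float:
    """Fraction of the compound's measurements that are detections."""
    ms = _of_compound(list(measurements), compound)
    return sum(m.detected for m in ms) / len(ms)


def percent_samples_positive(measurements: Iterable[Measurement]) -> float:
    """Fraction of distinct samples containing at least one detected compound."""
    measurements = list(measurements)
    if not measurements:
        raise DomainError("empty campaign")
    samples = {m.sample_key for m in measurements}
    positive = {m.sample_key for m in measurements if m.detected}
    return len(positive) / len(samples)


def percent_detections_below(
    measurements: Iterable[Measurement], threshold: float
) -> float:
    """Fraction of detections strictly below ``threshold`` ng/L."""
    detected = [m.value for m in measurements if m.detected]
    if not detected:
        raise DomainError("campaign has no detections")
    return sum(v < threshold for v in detected) / len(detected)


def detection_index(
    measurements: Iterable[Measurement],
    city: str,
    season: Optional[str] = None,
) -> float:
    """Positive detections across all compounds per distinct sample in a city."""
    ms = [m for m in measurements if m.city == city]
    if not ms:
        raise DomainError(f"city {city!r} absent from campaign")
    if season is not None:
        ms = [m for m in ms if m.season == season]
        if not ms:
            raise DomainError(f"city {city!r} has no {season!r}-season samples")
    n_samples = len({m.sample_key for m in ms})
    n_detections = sum(m.detected for m in ms)
    return n_detections / n_samples


def compound_summary(
    measurements: Iterable[Measurement],
    compound: str,
    censored_substitution: bool = False,
) -> dict:
    """Median/maximum of detected values plus detection frequency.

    With ``censored_substitution=True`` censored rows enter the median as
    LOQ/2 (sensitivity mode); the default median is over detections only.
    A compound with zero detections returns frequency 0 and ``None`` summary
    values.
    """
    ms = _of_compound(list(measurements), compound)
    detected = [m.value for m in ms if m.detected]
    frequency = len(detected) / len(ms)
    if not detected:
        return {
            "compound": compound,
            "detection_frequency": 0.0,
            "median_detected": None,
            "max_detected": None,
        }
    if censored_substitution:
        pool = detected + [m.loq / 2 for m in ms if not m.detected]
    else:
        pool = detected
    return {
        "compound": compound,
        "detection_frequency": frequency,
        "median_detected": float(np.median(pool)),
        "max_detected": float(max(detected)),
    }


def compound_maxima(measurements: Iterable[Measurement]) -> dict[str, float]:
    """Campaign-wide maximum detected concentration per compound (ng/L)."""
    maxima: dict[str, float] = {}
    for m in measurements:
        if m.detected and (m.compound not in maxima or m.value > maxima[m.compound]):
            maxima[m.compound] = m.value
    return maxima


def seasonal_comparison(measurements: Iterable[Measurement]) -> pd.DataFrame:
    """Per-compound dry/wet frequency, median and maximum.

    Compounds detected in exactly one season are flagged ``dry_exclusive`` /
    ``wet_exclusive``; a season with no rows at all yields NaN columns.
    """
    measurements = list(measurements)
    compounds = sorted({m.compound for m in measurements})
    rows = []
    for compound in compounds:
        row: dict = {"compound": compound}
        detected_in = {}
        for season in SEASONS:
            ms = [m for m in measurements if m.compound == compound and m.season == season]
            detected = [m.value for m in ms if m.detected]
            detected_in[season] = len(detected) > 0
            row[f"{season}_n"] = len(ms)
            row[f"{season}_frequency"] = (len(detected) / len(ms)) if ms else np.nan
            row[f"{season}_median"] = float(np.median(detected)) if detected else np.nan
            row[f"{season}_max"] = float(max(detected)) if detected else np.nan
        if detected_in["dry"] and not detected_in["wet"]:
            row["exclusive"] = "dry_exclusive"
        elif detected_in["wet"] and not detected_in["dry"]:
            row["exclusive"] = "wet_exclusive"
        else:
            row["exclusive"] = ""
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CampaignSummary:
    """Bundle of the campaign-level occurrence statistics."""

    per_compound: pd.DataFrame  # compound, detection_frequency, median, max
    per_city_index: pd.DataFrame  # city, season, detection_index, hot_spot
    percent_samples_positive: float
    percent_detections_below_threshold: float
    threshold_ng_L: float
    n_samples: int


def campaign_summary(
    measurements: Sequence[Measurement],
    threshold_ng_L: float = 50.0,
    hot_spot_index: float = HOT_SPOT_INDEX,
) -> CampaignSummary:
    """Compute the full occurrence summary for a campaign."""
    measurements = list(measurements)
    if not measurements:
        raise DomainError("empty campaign")
    compounds = sorted({m.compound for m in measurements})
    per_compound = pd.DataFrame(
        [compound_summary(measurements, c) for c in compounds]
    ).rename(columns={"median_detected": "median_ng_L", "max_detected": "max_ng_L"})
    city_rows = []
    for city in sorted({m.city for m in measurements}):
        seasons = sorted({m.season for m in measurements if m.city == city})
        for season in seasons:
            idx = detection_index(measurements, city, season)
            city_rows.append(
                {
                    "city": city,
                    "season": season,
                    "detection_index": idx,
                    "hot_spot": idx >= hot_spot_index,
                }
            )
        idx_all = detection_index(measurements, city)
        city_rows.append(
            {
                "city": city,
                "season": "all",
                "detection_index": idx_all,
                "hot_spot": idx_all >= hot_spot_index,
            }
        )
    any_detection = any(m.detected for m in measurements)
    return CampaignSummary(
        per_compound=per_compound,
        per_city_index=pd.DataFrame(city_rows),
        percent_samples_positive=percent_samples_positive(measurements),
        percent_detections_below_threshold=(
            percent_detections_below(measurements, threshold_ng_L)
            if any_detection
            else float("nan")
        ),
        threshold_ng_L=threshold_ng_L,
        n_samples=len({m.sample_key for m in measurements}),
    )
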