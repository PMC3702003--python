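"""Life-stage risk quotients, sensitivity scenarios and risk grouping.

The risk quotient of a compound at a life stage is the highest concentration
observed in the campaign divided by the stage's DWEL.  RQ >= 1 flags potential
concern.  For prioritisation, compounds are sorted into three screening
groups on their 12-interval RQ profile:

* Group 1 — at least one life-stage RQ >= 0.01,
* Group 2 — all life-stage RQs in [0.0001, 0.01),
* Group 3 — most (strictly more than half) life-stage RQs < 0.0001.

Profiles that satisfy neither the Group 2 all-above rule nor the Group 3
majority rule default to Group 2, keeping the three groups a partition.

Because the acceptable dose allocated to water scales with the relative
source contribution (RSC), RQs scale as 1/RSC; the sensitivity scenario
helper re-derives groups for alternative RSC allocations (e.g. the
conservative 20% case).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dwel import DWELProfile
from .errors import ValidationError

__all__ = [
    "GROUP1_THRESHOLD",
    "GROUP2_FLOOR",
    "RQProfile",
    "rq_profile",
    "classify_group",
    "rsc_sensitivity",
    "prioritize",
]

GROUP1_THRESHOLD = 0.01
GROUP2_FLOOR = 1.0e-4


@dataclass(frozen=True)
class RQProfile:
    """Per-life-stage risk quotients for one compound."""

    compound: str
    exposure_concentration: float  # ng/L, campaign maximum used as numerator
    rsc_used: float
    per_interval: dict  # interval label -> RQ, in age order
    group: int
    exceeds_unity: bool

    @property
    def values(self) -> np.ndarray:
        return np.array(list(self.per_interval.values()))

    @property
    def labels(self) -> list[str]:
        return list(self.per_interval.keys())

    def max_rq(self) -> float:
        return float(self.values.max())

    def min_rq(self) -> float:
        return float(self.values.min())

    def argmax_label(self) -> str:
        return self.labels[int(self.values.argmax())]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compound": self.compound,
                "interval": self.labels,
                "rq": self.values,
                "group": self.group,
                "rsc": self.rsc_used,
                "exceeds_unity": self.exceeds_unity,
            }
        )


def classify_group(rqs) -> int:
    """Apply the three-group screening rule to an RQ profile.

    Accepts an :class:`RQProfile` or any sequence of RQ values.
    """
    values = rqs.values if isinstance(rqs, RQProfile) else np.asarray(list(rqs), float)
    if values.size == 0:
        raise ValidationError("cannot classify an empty RQ profile")
    if values.max() >= GROUP1_THRESHOLD:
        return 1
    if (values >= GROUP2_FLOOR).all():
        return 2
    if (values < GROUP2_FLOOR).sum() * 2 > values.size:
        return 3
    return 2


def rq_profile(dwel: DWELProfile, max_concentration: float) -> RQProfile:
    """Divide the campaign maximum concentration by each life stage's DWEL."""
    if not math.isfinite(max_concentration) or max_concentration < 0:
        raise ValidationError(
            f"max_concentration must be >= 0 and finite, got {max_concentration}"
        )
    per_interval = {
        label: max_concentration / value for label, value in dwel.per_interval.items()
    }
    values = np.array(list(per_interval.values()))
    group = 3 if max_concentration == 0 else classify_group(values)
    return RQProfile(
        compound=dwel.compound,
        exposure_concentration=max_concentration,
        rsc_used=dwel.rsc_used,
        per_interval=per_interval,
        group=group,
        exceeds_unity=bool(values.max() >= 1.0),
    )


def _scaled(profile: RQProfile, rsc: float) -> RQProfile:
    """Re-express a profile at a different RSC (RQ scales as 1/RSC)."""
    factor = profile.rsc_used / rsc
    per_interval = {k: v * factor for k, v in profile.per_interval.items()}
    values = np.array(list(per_interval.values()))
    return RQProfile(
        compound=profile.compound,
        exposure_concentration=profile.exposure_concentration,
        rsc_used=rsc,
        per_interval=per_interval,
        group=3
        if profile.exposure_concentration == 0
        else classify_group(values),
        exceeds_unity=bool(values.max() >= 1.0) if values.size else False,
    )


def rsc_sensitivity(
    profile: RQProfile, rsc_values: Sequence[float]
) -> dict[float, RQProfile]:
    """Rescale an RQ profile to each RSC scenario and re-derive its group.

    Each scenario value must lie in (0, 1].  Scaling is exact: relative to an
    RSC = 1 profile, the scenario RQs are the base RQs times ``1/rsc``.
    """
    out: dict[float, RQProfile] = {}
    for rsc in rsc_values:
        if not (0 < rsc <= 1):
            raise ValidationError(f"rsc scenario {rsc} outside (0, 1]")
        out[rsc] = _scaled(profile, rsc)
    return out


def prioritize(profiles: Iterable[RQProfile]) -> pd.DataFrame:
    """Rank compounds for management priority.

    Sort key: compounds with any RQ >= 1 first, then group ascending, then
    maximum RQ descending; exact ties fall back to compound name so the
    ordering is deterministic.
    """
    profiles = list(profiles)
    rows = [
        {
            "compound": p.compound,
            "group": p.group,
            "max_rq": p.max_rq(),
            "max_rq_interval": p.argmax_label() if len(p.per_interval) else "",
            "exceeds_unity": p.exceeds_unity,
            "rsc": p.rsc_used,
            "exposure_concentration_ng_L": p.exposure_concentration,
        }
        for p in profiles
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "compound",
            "group",
            "max_rq",
            "max_rq_interval",
            "exceeds_unity",
            "rsc",
            "exposure_concentration_ng_L",
        ],
    )
    if df.empty:
        return df
    df = df.sort_values(
        by=["exceeds_unity", "group", "max_rq", "compound"],
        ascending=[False, True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return df
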