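"""End-to-end assessment assembly shared by the CLI and scripts.

Chains the pipeline stages: occurrence summary -> DWEL profiles -> RQ
profiles and groups -> indicator scenario, for a registry, an exposure-factor
table and either a measured campaign or a pre-computed per-compound maximum
table.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional, Sequence

import pandas as pd

from .dwel import dwel_profile
from .exposure_factors import ExposureFactorTable
from .indicators import IndicatorSelection, ScenarioFinding, interpret_scenario, select_indicators
from .risk import RQProfile, prioritize, rq_profile
from .toxicity import CompoundRecord

__all__ = [
    "load_reference_summary",
    "assess",
    "AssessmentResult",
]


def load_reference_summary() -> pd.DataFrame:
    """Packaged per-compound occurrence summary (frequency, median, max ng/L)."""
    ref = resources.files("aquarisk.data").joinpath("occurrence_reference_synthetic.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, comment="#")


@dataclass(frozen=True)
class AssessmentResult:
    """Everything one screening run produces."""

    profiles: dict  # rsc -> {compound -> RQProfile}
    priority: dict  # rsc -> ranked DataFrame
    not_assessable: tuple  # compounds lacking a toxicity basis or a maximum
    selection: IndicatorSelection
    scenario: ScenarioFinding

    def group_counts(self, rsc: float = 1.0) -> dict[int, int]:
        counts = {1: 0, 2: 0, 3: 0}
        for p in self.profiles[rsc].values():
            counts[p.group] += 1
        return counts


def assess(
    registry: Mapping[str, CompoundRecord],
    table: ExposureFactorTable,
    summary: pd.DataFrame,
    rsc_scenarios: Sequence[float] = (1.0,),
    min_indicator_frequency: float = 0.05,
    detected_compounds: Optional[set] = None,
) -> AssessmentResult:
    """Run the full screening assessment.

    ``summary`` needs columns ``compound``, ``detection_frequency``,
    ``median_ng_L`` and ``max_ng_L`` (campaign_summary per-compound output or
    the packaged reference).  ``rsc_scenarios`` are relative-source-
    contribution overrides; 1.0 reproduces the default screening case.
    ``detected_compounds`` restricts the indicator scenario to compounds
    actually seen in finished water (default: any compound with frequency > 0).
    """
    maxima = {
        str(r["compound"]): float(r["max_ng_L"])
        for _, r in summary.iterrows()
        if pd.notna(r["max_ng_L"])
    }
    profiles: dict[float, dict[str, RQProfile]] = {}
    priority: dict[float, pd.DataFrame] = {}
    skipped: list[str] = []
    for rsc in rsc_scenarios:
        per_compound: dict[str, RQProfile] = {}
        for name, rec in registry.items():
            if not rec.assessable or name not in maxima:
                if rsc == rsc_scenarios[0]:
                    skipped.append(name)
                continue
            # scenario RSCs scale each record's own allocation, so a 20%
            # scenario is conservative for every compound (caffeine's 0.1
            # default becomes 0.02, not 0.2)
            dwel = dwel_profile(rec, table, rsc_override=rsc * rec.rsc)
            per_compound[name] = rq_profile(dwel, maxima[name])
        profiles[rsc] = per_compound
        priority[rsc] = prioritize(per_compound.values())
    selection = select_indicators(registry, summary, min_frequency=min_indicator_frequency)
    if detected_compounds is None:
        detected_compounds = {
            str(r["compound"])
            for _, r in summary.iterrows()
            if float(r["detection_frequency"]) > 0
        }
    detected_groups = {
        a.group for a in selection.assignments if a.compound in detected_compounds
    }
    scenario = interpret_scenario(detected_groups)
    return AssessmentResult(
        profiles=profiles,
        priority=priority,
        not_assessable=tuple(skipped),
        selection=selection,
        scenario=scenario,
    )
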