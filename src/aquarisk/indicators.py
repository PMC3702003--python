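"""Indicator-based monitoring framework.

Routine quantification of dozens of pharmaceuticals is expensive; a small
suite of *indicator compounds* — frequently detected, origin-specific, with
known behaviour under chlorination (the dominant treatment step in the
surveyed systems) — can diagnose where contamination comes from and whether
treatment is working.  Indicators are placed in a 2x2 grid:

=========  ==================  ====================
group      origin              chlorination
=========  ==================  ====================
A          municipal           effective (treatable)
B          veterinary          effective (treatable)
C          municipal           ineffective
D          veterinary          ineffective
=========  ==================  ====================

Detecting an A or B indicator in finished water means a treatable compound
survived treatment: verify plant operation.  Detecting C or D reflects raw
source-water quality directly: trace and control contamination sources.
B and D additionally point at agricultural/veterinary inputs, A and C at
municipal sewage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Union

import pandas as pd

from .errors import DomainError
from .toxicity import CompoundRecord

__all__ = [
    "INDICATOR_GROUPS",
    "IndicatorAssignment",
    "IndicatorSelection",
    "ScenarioFinding",
    "assign_group",
    "select_indicators",
    "interpret_scenario",
]

INDICATOR_GROUPS = ("A", "B", "C", "D")

_GROUP_OF = {
    ("municipal", True): "A",
    ("veterinary", True): "B",
    ("municipal", False): "C",
    ("veterinary", False): "D",
}


def assign_group(origin: str, treatable: bool) -> str:
    """Map (origin, chlorination treatability) to indicator group A–D.

    Compounds of mixed origin cannot serve as indicators and raise
    :class:`DomainError`.
    """
    if origin == "both":
        raise DomainError("indicator compounds must be origin-specific, not 'both'")
    try:
        return _GROUP_OF[(origin, bool(treatable))]
    except KeyError:
        raise DomainError(f"unknown origin {origin!r}") from None


@dataclass(frozen=True)
class IndicatorAssignment:
    compound: str
    origin: str
    treatable_by_chlorination: bool
    group: str
    detection_frequency: float
    median_ng_L: float


@dataclass(frozen=True)
class IndicatorSelection:
    assignments: tuple  # IndicatorAssignment, ranked within group
    uncovered_groups: tuple  # groups with no eligible candidate

    def by_group(self) -> dict[str, list[IndicatorAssignment]]:
        out: dict[str, list[IndicatorAssignment]] = {g: [] for g in INDICATOR_GROUPS}
        for a in self.assignments:
            out[a.group].append(a)
        return out

    def compounds(self) -> set[str]:
        return {a.compound for a in self.assignments}


def select_indicators(
    registry: Mapping[str, CompoundRecord],
    summary: Union[pd.DataFrame, Mapping[str, Mapping]],
    min_frequency: float = 0.05,
    per_group: int = 2,
) -> IndicatorSelection:
    """Choose indicator compounds from a registry and an occurrence summary.

    Eligibility: unambiguous origin (``municipal`` or ``veterinary``, never
    ``both``) and detection frequency >= ``min_frequency``.  Candidates are
    ranked within each group by frequency, then median detected level, and at
    most ``per_group`` are retained per group (``per_group=None`` keeps all).
    Groups left without a candidate are reported as uncovered, not errors.

    ``summary`` is a data frame with columns ``compound``,
    ``detection_frequency`` and ``median_ng_L`` (as produced by
    :func:`aquarisk.occurrence.campaign_summary`) or an equivalent mapping.
    """
    if isinstance(summary, pd.DataFrame):
        stats = {
            str(r["compound"]): (
                float(r["detection_frequency"]),
                float(r["median_ng_L"]) if pd.notna(r["median_ng_L"]) else 0.0,
            )
            for _, r in summary.iterrows()
        }
    else:
        stats = {
            c: (float(v["detection_frequency"]), float(v.get("median_ng_L", 0.0) or 0.0))
            for c, v in summary.items()
        }
    candidates: dict[str, list[IndicatorAssignment]] = {g: [] for g in INDICATOR_GROUPS}
    for name, rec in registry.items():
        if rec.origin == "both":
            continue
        if name not in stats:
            continue
        freq, median = stats[name]
        if freq < min_frequency:
            continue
        group = assign_group(rec.origin, rec.chlorination_treatable)
        candidates[group].append(
            IndicatorAssignment(
                compound=name,
                origin=rec.origin,
                treatable_by_chlorination=rec.chlorination_treatable,
                group=group,
                detection_frequency=freq,
                median_ng_L=median,
            )
        )
    assignments: list[IndicatorAssignment] = []
    uncovered: list[str] = []
    for group in INDICATOR_GROUPS:
        ranked = sorted(
            candidates[group],
            key=lambda a: (-a.detection_frequency, -a.median_ng_L, a.compound),
        )
        if per_group is not None:
            ranked = ranked[:per_group]
        if ranked:
            assignments.extend(ranked)
        else:
            uncovered.append(group)
    return IndicatorSelection(assignments=tuple(assignments), uncovered_groups=tuple(uncovered))


@dataclass(frozen=True)
class ScenarioFinding:
    """Interpretation of which indicator groups were detected in finished water."""

    groups_detected: frozenset
    findings: tuple  # ordered finding tags
    recommendations: tuple  # ordered action tags
    interpretation: str


_FINDING_TEXT = {
    "treatment_verification": (
        "a chlorination-treatable indicator reached finished water: treatment "
        "may be operating ineffectively and/or raw-water quality is poor"
    ),
    "source_impact": (
        "a chlorination-resistant indicator is present: raw water sources are "
        "negatively impacted by wastewater inputs"
    ),
    "municipal_origin": "municipal sewage inputs are implicated",
    "veterinary_origin": "veterinary/agricultural inputs are implicated",
}

_RECOMMENDATIONS = {
    "treatment_verification": ("verify_dwtp_operating_conditions",),
    "source_impact": (
        "trace_contamination_sources",
        "short_term_source_control",
        "long_term_regulatory_measures",
        "consider_treatment_upgrade",
    ),
}


def interpret_scenario(detected: Iterable[str]) -> ScenarioFinding:
    """Turn a set of detected indicator groups into findings and actions.

    Monotone by construction: enlarging the detected set can only add
    findings and recommendations, never remove them.
    """
    groups = frozenset(detected)
    unknown = groups - set(INDICATOR_GROUPS)
    if unknown:
        raise DomainError(f"unknown indicator groups: {sorted(unknown)}")
    findings: list[str] = []
    recommendations: list[str] = []
    if groups & {"A", "B"}:
        findings.append("treatment_verification")
        recommendations.extend(_RECOMMENDATIONS["treatment_verification"])
    if groups & {"C", "D"}:
        findings.append("source_impact")
        recommendations.extend(_RECOMMENDATIONS["source_impact"])
    if groups & {"A", "C"}:
        findings.append("municipal_origin")
    if groups & {"B", "D"}:
        findings.append("veterinary_origin")
    if not groups:
        interpretation = "no indicator detected; no action required"
    else:
        interpretation = "; ".join(_FINDING_TEXT[f] for f in findings)
    return ScenarioFinding(
        groups_detected=groups,
        findings=tuple(findings),
        recommendations=tuple(dict.fromkeys(recommendations)),
        interpretation=interpretation,
    )
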