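"""Toxicity bases: acceptable daily intakes and risk-specific doses.

Each compound carries one or more *toxicity bases*, each derived through one
of four routes:

``toxicological``
    chronic-study NOAEL/LOAEL divided by a composite uncertainty factor
    (inter-/intra-species extrapolation, LOAEL-to-NOAEL, database quality),
``therapeutic``
    lowest daily therapeutic dose divided by an uncertainty factor,
``microbiological``
    intake derived from minimum inhibitory concentrations against human gut
    flora, divided by a composite factor,
``carcinogenic``
    maximum tolerated dose (MTD) from a chronic bioassay extrapolated linearly
    down to a risk-specific dose (RSD) at a stated incremental lifetime cancer
    risk; the extrapolation divisor is folded into the composite factor.

All routes reduce to ``derived_dose = pod / composite_uncertainty_factor`` in
µg/kg/day.  Screening uses the *most restrictive* (minimum) derived dose per
compound.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .errors import NotAssessableError, ParseError, ValidationError

__all__ = [
    "ROUTES",
    "POD_KINDS",
    "PointOfDeparture",
    "ToxicityBasis",
    "CompoundRecord",
    "derive_dose",
    "most_restrictive",
    "load_registry",
    "default_registry",
]

logger = logging.getLogger(__name__)

ROUTES = ("toxicological", "therapeutic", "microbiological", "carcinogenic")
POD_KINDS = ("NOAEL", "LOAEL", "lowest_therapeutic_dose", "MIC_derived_intake", "MTD")

#: tie-break priority for most_restrictive (lower = preferred)
_ROUTE_PRIORITY = {r: i for i, r in enumerate(
    ("carcinogenic", "toxicological", "microbiological", "therapeutic")
)}

ORIGINS = ("municipal", "veterinary", "both")


@dataclass(frozen=True)
class PointOfDeparture:
    """A toxicological point of departure in µg/kg body weight/day."""

    value: float
    pod_kind: str
    endpoint: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        if not (self.value > 0) or not math.isfinite(self.value):
            raise ValidationError("point of departure must be positive and finite")
        if self.pod_kind not in POD_KINDS:
            raise ValidationError(
                f"unknown pod_kind {self.pod_kind!r}; expected one of {POD_KINDS}"
            )


@dataclass(frozen=True)
class ToxicityBasis:
    """An ADI or RSD with its derivation provenance.

    ``derived_dose`` always equals ``pod.value / composite_uncertainty_factor``
    (enforced on construction); for the carcinogenic route the MTD-to-RSD
    linear-extrapolation divisor at ``target_risk_level`` is folded into the
    composite factor.
    """

    compound: str
    route: str
    pod: PointOfDeparture
    composite_uncertainty_factor: float
    derived_dose: float
    target_risk_level: Optional[float] = None
    factors: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.route not in ROUTES:
            raise ValidationError(f"unknown route {self.route!r}")
        if self.composite_uncertainty_factor < 1:
            raise ValidationError("composite uncertainty factor must be >= 1")
        expected = self.pod.value / self.composite_uncertainty_factor
        if not math.isclose(self.derived_dose, expected, rel_tol=1e-9):
            raise ValidationError(
                f"{self.compound}: derived_dose {self.derived_dose} != "
                f"pod/UF = {expected}"
            )
        if not (self.derived_dose > 0):
            raise ValidationError("derived dose must be positive")
        if self.route == "carcinogenic":
            if self.target_risk_level is None:
                raise ValidationError("carcinogenic route requires target_risk_level")
            if not (0 < self.target_risk_level < 1):
                raise ValidationError("target_risk_level must be a small fraction")


def derive_dose(
    pod: PointOfDeparture,
    route: str,
    factors: Sequence[float],
    target_risk_level: Optional[float] = None,
    compound: str = "",
) -> ToxicityBasis:
    """Divide a point of departure by named factors to obtain an ADI or RSD.

    ``factors`` are dimensionless divisors (each >= 1); their product is the
    composite uncertainty factor.  The carcinogenic route requires an MTD-kind
    point of departure and a ``target_risk_level`` (e.g. ``1e-6``), the linear
    extrapolation divisor being supplied as one of the factors.
    """
    if route not in ROUTES:
        raise ValidationError(f"unknown route {route!r}")
    factors = tuple(float(f) for f in factors)
    for f in factors:
        if not (f > 0) or not math.isfinite(f):
            raise ValidationError(f"non-positive or non-finite factor {f}")
        if f < 1:
            raise ValidationError(f"uncertainty factor {f} < 1 is not allowed")
    if route == "carcinogenic":
        if pod.pod_kind != "MTD":
            raise ValidationError("carcinogenic route requires an MTD point of departure")
        if target_risk_level is None:
            raise ValidationError("carcinogenic route requires target_risk_level")
    if not factors and pod.pod_kind in ("NOAEL", "LOAEL"):
        logger.warning(
            "%s: deriving dose from %s with no uncertainty factors (UF = 1)",
            compound or "<unnamed>",
            pod.pod_kind,
        )
    composite = math.prod(factors) if factors else 1.0
    return ToxicityBasis(
        compound=compound,
        route=route,
        pod=pod,
        composite_uncertainty_factor=composite,
        derived_dose=pod.value / composite,
        target_risk_level=target_risk_level,
        factors=factors,
    )


def most_restrictive(bases: Iterable[ToxicityBasis]) -> ToxicityBasis:
    """Return the basis with the minimum derived dose.

    Ties are broken by route priority (carcinogenic > toxicological >
    microbiological > therapeutic), i.e. the route with the graver endpoint
    class wins an exact tie.
    """
    bases = list(bases)
    if not bases:
        raise ValidationError("most_restrictive requires a non-empty collection")
    return min(bases, key=lambda b: (b.derived_dose, _ROUTE_PRIORITY[b.route]))


@dataclass(frozen=True)
class CompoundRecord:
    """Registry entry: identity, sources, treatability and toxicity bases.

    ``rsc`` is the relative source contribution allocated to drinking water,
    a fraction in (0, 1]; the screening default is 1.0 (all of the acceptable
    dose allotted to tap water) except for compounds with dominant non-water
    exposure such as caffeine (0.1).
    """

    compound: str
    therapeutic_class: str = ""
    origin: str = "municipal"
    chlorination_treatable: bool = False
    bases: tuple = field(default_factory=tuple)
    rsc: float = 1.0
    notes: str = ""

    def __post_init__(self) -> None:
        if self.origin not in ORIGINS:
            raise ValidationError(
                f"{self.compound}: origin must be one of {ORIGINS}, got {self.origin!r}"
            )
        if not (0 < self.rsc <= 1):
            raise ValidationError(f"{self.compound}: rsc must lie in (0, 1]")

    @property
    def assessable(self) -> bool:
        return len(self.bases) > 0

    def selected_basis(self) -> ToxicityBasis:
        if not self.bases:
            raise NotAssessableError(
                f"{self.compound}: no toxicity basis; compound is not assessable"
            )
        return most_restrictive(self.bases)


_REGISTRY_COLUMNS = (
    "compound",
    "therapeutic_class",
    "origin",
    "chlorination_treatable",
    "route",
    "pod_value_ug_kg_day",
    "pod_kind",
    "endpoint",
    "composite_uf",
    "target_risk_level",
    "rsc",
)


def _registry_from_frame(df: pd.DataFrame) -> dict[str, CompoundRecord]:
    missing = [c for c in _REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"registry missing columns: {missing}")
    records: dict[str, CompoundRecord] = {}
    for compound, grp in df.groupby("compound", sort=False):
        head = grp.iloc[0]
        bases = []
        for i, row in grp.iterrows():
            if pd.isna(row["route"]) or str(row["route"]).strip() == "":
                continue  # compound listed without a toxicity basis
            try:
                pod = PointOfDeparture(
                    value=float(row["pod_value_ug_kg_day"]),
                    pod_kind=str(row["pod_kind"]),
                    endpoint="" if pd.isna(row["endpoint"]) else str(row["endpoint"]),
                )
                trl = row["target_risk_level"]
                trl = None if pd.isna(trl) else float(trl)
                uf = float(row["composite_uf"])
                bases.append(
                    ToxicityBasis(
                        compound=str(compound),
                        route=str(row["route"]),
                        pod=pod,
                        composite_uncertainty_factor=uf,
                        derived_dose=pod.value / uf,
                        target_risk_level=trl,
                    )
                )
            except (TypeError, ValueError) as exc:
                raise ParseError(f"registry row {i} ({compound}) malformed: {exc}") from exc
        records[str(compound)] = CompoundRecord(
            compound=str(compound),
            therapeutic_class=str(head["therapeutic_class"]),
            origin=str(head["origin"]),
            chlorination_treatable=_parse_bool(head["chlorination_treatable"]),
            bases=tuple(bases),
            rsc=1.0 if pd.isna(head["rsc"]) else float(head["rsc"]),
        )
    return records


def _parse_bool(x) -> bool:
    if isinstance(x, bool):
        return x
    s = str(x).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ParseError(f"cannot interpret {x!r} as boolean")


def load_registry(source: Union[str, Path]) -> dict[str, CompoundRecord]:
    """Load a compound registry from a delimiter-separated file.

    One row per toxicity basis; multiple rows per compound are merged into a
    single :class:`CompoundRecord` (compound-level attributes taken from the
    first row).  Rows with an empty ``route`` register the compound without a
    basis (flagged not assessable).
    """
    path = Path(source)
    if not path.exists():
        raise ParseError(f"registry file not found: {path}")
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise ParseError(f"cannot parse registry file {path}: {exc}") from exc
    return _registry_from_frame(df)


def default_registry() -> dict[str, CompoundRecord]:
    """The packaged registry of the 17 compounds detected in the tap-water survey."""
    ref = resources.files("aquarisk.data").joinpath("compound_registry_synthetic.csv")
    with resources.as_file(ref) as path:
        return load_registry(path)


def registry_to_frame(records: Mapping[str, CompoundRecord]) -> pd.DataFrame:
    """Flatten a registry back to its one-row-per-basis tabular form."""
    rows = []
    for rec in records.values():
        if not rec.bases:
            rows.append(
                {
                    "compound": rec.compound,
                    "therapeutic_class": rec.therapeutic_class,
                    "origin": rec.origin,
                    "chlorination_treatable": rec.chlorination_treatable,
                    "route": "",
                    "pod_value_ug_kg_day": float("nan"),
                    "pod_kind": "",
                    "endpoint": "",
                    "composite_uf": float("nan"),
                    "target_risk_level": float("nan"),
                    "rsc": rec.rsc,
                }
            )
        for b in rec.bases:
            rows.append(
                {
                    "compound": rec.compound,
                    "therapeutic_class": rec.therapeutic_class,
                    "origin": rec.origin,
                    "chlorination_treatable": rec.chlorination_treatable,
                    "route": b.route,
                    "pod_value_ug_kg_day": b.pod.value,
                    "pod_kind": b.pod.pod_kind,
                    "endpoint": b.pod.endpoint,
                    "composite_uf": b.composite_uncertainty_factor,
                    "target_risk_level": b.target_risk_level,
                    "rsc": rec.rsc,
                }
            )
    return pd.DataFrame(rows)
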