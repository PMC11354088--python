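"""Indicator and area metadata types, registry loading and structural checks.

The registry is the single source of truth for indicator semantics: which
thematic domain an indicator belongs to and whether a high raw value is
favourable (``HIGH_GOOD``) or unfavourable (``LOW_GOOD``) for resilience.
A reference registry of 44 indicators ships as package data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BRIC_DOMAINS",
    "DIRECTIONS",
    "REGIONS",
    "RURALITY_CLASSES",
    "THEMES",
    "AreaMeta",
    "AreaTable",
    "IndicatorMeta",
    "Registry",
    "RegistryError",
    "ValidationError",
    "apply_exclusions",
    "bundled_registry_path",
    "check_indicator_count",
    "load_bundled_registry",
    "load_registry",
]

BRIC_DOMAINS = (
    "social",
    "economic",
    "institutional",
    "infrastructure",
    "environmental",
    "community_capital",
)

DIRECTIONS = ("HIGH_GOOD", "LOW_GOOD")

#: The nine English regions used for the geographic comparisons.
REGIONS = (
    "North East",
    "North West",
    "Yorkshire and The Humber",
    "East Midlands",
    "West Midlands",
    "East of England",
    "London",
    "South East",
    "South West",
)

RURALITY_CLASSES = (
    "predominantly_urban",
    "urban_with_significant_rural",
    "predominantly_rural",
)

#: Theme vocabulary (union over the six domains' theme lists).
THEMES = frozenset(
    {
        "Demographic",
        "Health/well-being",
        "Education/skills",
        "Language/communication",
        "Transport",
        "Food",
        "Civic engagement",
        "Labour market",
        "Community cohesion",
        "Equity",
        "Income/savings/debt",
        "Commerce/retail",
        "Housing",
        "Economic output",
        "Local government",
        "Mitigation",
        "Disaster-specific",
        "Emergency services",
        "Energy/water",
        "Shelter capacity",
        "Land type/use",
        "Green space/forests",
        "Waste/pollution",
        "Soil/erosion",
        "Climate/elevation",
        "Political engagement",
        "Religion",
        "Culture/sports",
        "Other",
    }
)


class ValidationError(ValueError):
    """Raised when metadata violates a structural contract."""


class RegistryError(ValidationError):
    """Raised for malformed registry files."""


@dataclass(frozen=True)
class IndicatorMeta:
    """Semantics of a single indicator column."""

    id: str
    name: str
    theme: str
    bric_domain: str
    direction: str
    source: str = ""
    year: str = ""

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValidationError(
                f"indicator {self.id!r}: unknown direction {self.direction!r}; "
                f"expected one of {DIRECTIONS}"
            )
        if self.bric_domain not in BRIC_DOMAINS:
            raise ValidationError(
                f"indicator {self.id!r}: unknown domain {self.bric_domain!r}; "
                f"expected one of {BRIC_DOMAINS}"
            )
        if self.theme not in THEMES:
            raise ValidationError(
                f"indicator {self.id!r}: theme {self.theme!r} not in vocabulary"
            )

    @property
    def high_good(self) -> bool:
        return self.direction == "HIGH_GOOD"


@dataclass(frozen=True)
class Registry:
    """Ordered, id-unique collection of :class:`IndicatorMeta`."""

    indicators: tuple[IndicatorMeta, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for ind in self.indicators:
            if ind.id in seen:
                raise RegistryError(f"duplicate indicator id {ind.id!r}")
            seen.add(ind.id)

    def __len__(self) -> int:
        return len(self.indicators)

    def __iter__(self):
        return iter(self.indicators)

    def __getitem__(self, indicator_id: str) -> IndicatorMeta:
        for ind in self.indicators:
            if ind.id == indicator_id:
                return ind
        raise KeyError(indicator_id)

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.indicators]

    @property
    def directions(self) -> pd.Series:
        return pd.Series(
            [ind.direction for ind in self.indicators], index=self.ids, name="direction"
        )

    def domain_members(self) -> dict[str, list[str]]:
        """Indicator ids grouped by thematic domain, registry order preserved."""
        members: dict[str, list[str]] = {d: [] for d in BRIC_DOMAINS}
        for ind in self.indicators:
            members[ind.bric_domain].append(ind.id)
        return members

    def domain_counts(self) -> dict[str, int]:
        return {d: len(m) for d, m in self.domain_members().items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id": i.id,
                    "name": i.name,
                    "theme": i.theme,
                    "bric_domain": i.bric_domain,
                    "direction": i.direction,
                    "source": i.source,
                    "year": i.year,
                }
                for i in self.indicators
            ]
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class AreaMeta:
    """Metadata for one area (district-level geography)."""

    area_id: str
    name: str = ""
    region: str = ""
    coastal: bool = False
    rurality: str = "predominantly_urban"
    population: float = 0.0
    upper_tier_id: str | None = None
    peer_group: str | None = None

    def __post_init__(self) -> None:
        if self.population < 0:
            raise ValidationError(
                f"area {self.area_id!r}: population must be non-negative"
            )
        if self.rurality not in RURALITY_CLASSES:
            raise ValidationError(
                f"area {self.area_id!r}: unknown rurality {self.rurality!r}"
            )
        if self.region and self.region not in REGIONS:
            raise ValidationError(
                f"area {self.area_id!r}: unknown region {self.region!r}"
            )


@dataclass
class AreaTable:
    """Areas x indicators numeric matrix plus metadata.

    ``values`` is a DataFrame indexed by area_id with one column per
    registry indicator (NaN marks missing cells).
    """

    areas: tuple[AreaMeta, ...]
    values: pd.DataFrame
    registry: Registry

    def __post_init__(self) -> None:
        ids = [a.area_id for a in self.areas]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate area ids")
        if list(self.values.index) != ids:
            raise ValidationError("values index does not match area metadata order")
        if list(self.values.columns) != self.registry.ids:
            raise ValidationError("values columns do not match registry order")
        self.values.index.name = "area_id"

    @property
    def n_areas(self) -> int:
        return len(self.areas)

    @property
    def n_indicators(self) -> int:
        return len(self.registry)

    @property
    def area_ids(self) -> list[str]:
        return [a.area_id for a in self.areas]

    def area_meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "area_id": a.area_id,
                    "name": a.name,
                    "region": a.region,
                    "coastal": a.coastal,
                    "rurality": a.rurality,
                    "population": a.population,
                    "upper_tier_id": a.upper_tier_id if a.upper_tier_id else "",
                    "peer_group": a.peer_group if a.peer_group else "",
                }
                for a in self.areas
            ]
        ).set_index("area_id")

    def copy(self) -> "AreaTable":
        return AreaTable(self.areas, self.values.copy(), self.registry)

    def write(self, values_path: str | Path, meta_path: str | Path | None = None) -> None:
        self.values.to_csv(values_path, index_label="area_id")
        if meta_path is not None:
            self.area_meta_frame().to_csv(meta_path)

    @classmethod
    def read(
        cls,
        values_path: str | Path,
        registry: Registry,
        meta_path: str | Path | None = None,
    ) -> "AreaTable":
        values = pd.read_csv(values_path, index_col="area_id")
        values.index = values.index.astype(str)
        if meta_path is not None:
            meta = pd.read_csv(meta_path, index_col="area_id", keep_default_na=False)
            meta.index = meta.index.astype(str)
            areas = tuple(
                AreaMeta(
                    area_id=str(aid),
                    name=str(row.get("name", "")),
                    region=str(row.get("region", "")),
                    coastal=str(row.get("coastal", "False")) in ("True", "true", "1"),
                    rurality=str(row.get("rurality", "predominantly_urban")),
                    population=float(row.get("population", 0.0) or 0.0),
                    upper_tier_id=str(row["upper_tier_id"]) or None
                    if "upper_tier_id" in row
                    else None,
                    peer_group=str(row["peer_group"]) or None
                    if "peer_group" in row
                    else None,
                )
                for aid, row in meta.iterrows()
            )
        else:
            areas = tuple(AreaMeta(area_id=str(aid)) for aid in values.index)
        return cls(areas, values[registry.ids], registry)


def load_registry(path: str | Path) -> Registry:
    """Load and validate an indicator registry from a CSV file.

    The file must have one row per indicator with columns
    ``id,name,theme,bric_domain,direction[,source,year]``. File order is
    preserved. Duplicate ids and unrecognised direction/domain tokens raise
    :class:`RegistryError` naming the offending value.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if frame.empty:
        raise RegistryError(f"registry file {path} contains no indicators")
    required = {"id", "name", "theme", "bric_domain", "direction"}
    missing = required - set(frame.columns)
    if missing:
        raise RegistryError(f"registry file missing columns: {sorted(missing)}")
    indicators = []
    for _, row in frame.iterrows():
        indicators.append(
            IndicatorMeta(
                id=row["id"],
                name=row["name"],
                theme=row["theme"],
                bric_domain=row["bric_domain"],
                direction=row["direction"],
                source=row.get("source", ""),
                year=row.get("year", ""),
            )
        )
    return Registry(tuple(indicators))


def bundled_registry_path() -> Path:
    return Path(resources.files("resindex") / "data" / "indicator_registry.csv")


def load_bundled_registry() -> Registry:
    """The packaged 44-indicator reference registry."""
    return load_registry(bundled_registry_path())


def apply_exclusions(
    table: AreaTable, excluded_ids: Sequence[str], strict: bool = True
) -> AreaTable:
    """Drop named areas from a table, preserving the order of the rest.

    With ``strict=True`` (default) an unknown id raises; otherwise it is
    skipped. Excluding every area is always an error.
    """
    known = set(table.area_ids)
    excluded = []
    for aid in excluded_ids:
        if aid not in known:
            if strict:
                raise ValidationError(f"cannot exclude unknown area {aid!r}")
            continue
        excluded.append(aid)
    excluded_set = set(excluded)
    keep = [a for a in table.areas if a.area_id not in excluded_set]
    if not keep:
        raise ValidationError("exclusions would remove every area")
    return AreaTable(
        tuple(keep), table.values.drop(index=list(excluded_set)), table.registry
    )


@dataclass(frozen=True)
class IndicatorCountReport:
    lower: int
    upper: int
    within: bool


def check_indicator_count(
    n_areas: int,
    n_indicators: int,
    min_obs_per_var: int = 5,
    max_obs_per_var: int = 10,
) -> IndicatorCountReport:
    """Admissible indicator-count range under an observations-per-variable rule.

    With ``n_areas`` observations and a rule of ``min_obs_per_var`` to
    ``max_obs_per_var`` observations per variable, the admissible number of
    indicators runs from ``ceil(n_areas / max_obs_per_var)`` to
    ``floor(n_areas / min_obs_per_var)``.
    """
    if n_areas <= 0 or n_indicators <= 0:
        raise ValidationError("counts must be positive")
    if min_obs_per_var <= 0 or max_obs_per_var <= 0:
        raise ValidationError("observations-per-variable bounds must be positive")
    lower = math.ceil(n_areas / max_obs_per_var)
    upper = math.floor(n_areas / min_obs_per_var)
    return IndicatorCountReport(lower, upper, lower <= n_indicators <= upper)
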