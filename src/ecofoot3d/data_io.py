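"""Domain types, packaged constant tables, and readers/writers.

The pipeline consumes three tables:

* a land-type factor table (equivalence factor r_j and yield factor y_j per
  bioproductive land type),
* a consumption-item yield table (provincial-hectare average yields for
  biological items; energy-footprint density and calorific conversion
  coefficients for energy items),
* a long-format city-year panel (population, per-capita consumptions,
  per-capita land areas, and the nine socioeconomic indicators X1-X9).

Defaults packaged under ``ecofoot3d/data`` carry the provincial-hectare
constants for the Chengdu urban agglomeration.
"""

from __future__ import annotations

import enum
import hashlib
import logging
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

INDICATOR_NAMES = tuple(f"X{i}" for i in range(1, 10))

#: indicator -> perspective, following the standard economy/society/environment split
INDICATOR_CATEGORIES: Mapping[str, str] = {
    "X1": "economic",
    "X2": "economic",
    "X3": "social",
    "X4": "social",
    "X5": "social",
    "X6": "environment",
    "X7": "environment",
    "X8": "environment",
    "X9": "environment",
}


class LandType(enum.Enum):
    """The six bioproductive land types of the accounting framework."""

    CROPLANDS = "croplands"
    FORESTS = "forests"
    GRAZING_LANDS = "grazing_lands"
    FISHING_GROUNDS = "fishing_grounds"
    CARBON_CAPTURE_LAND = "carbon_capture_land"
    BUILT_UP = "built_up"

    def __str__(self) -> str:  # CSV-friendly
        return self.value


#: common spelling variants normalized on read
_LAND_ALIASES = {
    "built-up area": "built_up",
    "built-up areas": "built_up",
    "built_up_area": "built_up",
    "built_up_areas": "built_up",
    "cropland": "croplands",
    "forest": "forests",
    "grazing land": "grazing_lands",
    "grazing_land": "grazing_lands",
    "fishing ground": "fishing_grounds",
    "fishing_ground": "fishing_grounds",
    "fossil energy land": "carbon_capture_land",
}


def parse_land_type(name: str) -> LandType:
    key = str(name).strip().lower().replace("’", "'")
    key = _LAND_ALIASES.get(key, key)
    try:
        return LandType(key)
    except ValueError:
        raise ValidationError(f"unknown land type: {name!r}") from None


@dataclass(frozen=True)
class LandTypeFactor:
    """Equivalence factor r_j and yield factor y_j for one land type.

    The equivalence factor converts physical hectares of a land type into
    standardized (here provincial) hectares of world-average productivity;
    the yield factor scales for the region's productivity relative to the
    provincial average.  Carbon-capture (fossil-energy) land carries a yield
    factor of zero: no carrying capacity is reserved for CO2 uptake.
    """

    land_type: LandType
    equivalence_factor: float
    yield_factor: float

    def __post_init__(self) -> None:
        if not self.equivalence_factor > 0:
            raise ValidationError(
                f"{self.land_type}: equivalence_factor must be > 0, "
                f"got {self.equivalence_factor}"
            )
        if self.yield_factor < 0:
            raise ValidationError(
                f"{self.land_type}: yield_factor must be >= 0, got {self.yield_factor}"
            )
        if self.yield_factor == 0 and self.land_type is not LandType.CARBON_CAPTURE_LAND:
            raise ValidationError(
                f"{self.land_type}: only carbon_capture_land may have yield_factor 0"
            )


class Account(enum.Enum):
    BIOLOGICAL = "biological"
    ENERGY = "energy"


@dataclass(frozen=True)
class ConsumptionItem:
    """One consumer-good item and its land-conversion constants.

    Biological items convert mass to area through the provincial-hectare
    average yield (kg/hm2).  Energy items convert the declared consumption
    unit to GJ (``convert_coefficient``) and GJ to area through the
    energy-footprint density (GJ/hm2) of their land type.
    """

    name: str
    land_type: LandType
    account: Account
    average_yield: float | None = None  # kg/hm2, biological only
    energy_footprint_density: float | None = None  # GJ/hm2, energy only
    convert_coefficient: float | None = None  # GJ per declared unit, energy only
    unit: str = ""

    def __post_init__(self) -> None:
        if self.account is Account.BIOLOGICAL:
            if self.average_yield is None or not self.average_yield > 0:
                raise ValidationError(f"{self.name}: biological item needs average_yield > 0")
            if self.energy_footprint_density is not None or self.convert_coefficient is not None:
                raise ValidationError(f"{self.name}: biological item must not carry energy fields")
        else:
            if self.average_yield is not None:
                raise ValidationError(f"{self.name}: energy item must not carry average_yield")
            if self.energy_footprint_density is None or not self.energy_footprint_density > 0:
                raise ValidationError(f"{self.name}: energy item needs energy_footprint_density > 0")
            if self.convert_coefficient is None or not self.convert_coefficient > 0:
                raise ValidationError(f"{self.name}: energy item needs convert_coefficient > 0")


@dataclass(frozen=True)
class CityYearRecord:
    """One city-year observation of the panel.

    ``consumption`` maps item name to PER-CAPITA quantity (kg/cap for
    biological items, declared energy unit per capita for energy items);
    ``land_area`` maps land type to per-capita bioproductive area (hm2/cap);
    ``indicators`` is the ordered X1..X9 vector.
    """

    city: str
    year: int
    population: float
    consumption: Mapping[str, float]
    land_area: Mapping[LandType, float]
    indicators: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.population > 0:
            raise ValidationError(f"{self.city}/{self.year}: population must be > 0")
        for name, value in self.consumption.items():
            if value < 0 or not math.isfinite(value):
                raise ValidationError(
                    f"{self.city}/{self.year}: negative or non-finite consumption for {name}"
                )
        for land, value in self.land_area.items():
            if value < 0 or not math.isfinite(value):
                raise ValidationError(
                    f"{self.city}/{self.year}: negative or non-finite area for {land}"
                )
        if len(self.indicators) != len(INDICATOR_NAMES):
            raise ValidationError(
                f"{self.city}/{self.year}: expected {len(INDICATOR_NAMES)} indicators, "
                f"got {len(self.indicators)}"
            )


@dataclass
class AnalysisConfig:
    """Tunable parameters of the whole pipeline.

    ``biodiversity_retention`` is the fraction of biocapacity left after the
    12% biodiversity set-aside.  Random-forest parameters follow the common
    regression defaults (ntree = 500, mtry = p/3, minimum leaf 5).
    """

    biodiversity_retention: float = 0.88
    n_trees: int = 500
    mtry: int | None = None  # None -> max(1, p // 3)
    min_leaf: int = 5
    seed: int = 0
    k_clusters: int = 4
    linkage: str = "ward"
    standardize_scope: str = "pooled"  # or "per_year"
    negative_vi: str = "truncate"  # or "absolute"
    per_capita_consumption: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.biodiversity_retention <= 1:
            raise ValidationError("biodiversity_retention must be in (0, 1]")
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")
        if self.k_clusters < 2:
            raise ValidationError("k_clusters must be >= 2")
        if self.negative_vi not in ("truncate", "absolute"):
            raise ValidationError("negative_vi must be 'truncate' or 'absolute'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise SchemaError(f"{path}: config must be a mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def content_hash(self) -> str:
        payload = yaml.safe_dump(
            {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# readers


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def load_factor_table(path: str | Path | None = None) -> list[LandTypeFactor]:
    """Read a land-type factor CSV; ``None`` loads the packaged defaults."""
    if path is None:
        path = resources.files("ecofoot3d.data") / "factors.csv"
    df = pd.read_csv(path)
    _require_columns(df, ["land_type", "equivalence_factor", "yield_factor"], path)
    factors = []
    seen: set[LandType] = set()
    for row in df.itertuples(index=False):
        land = parse_land_type(row.land_type)
        if land in seen:
            raise ValidationError(f"{path}: duplicate land type {land}")
        seen.add(land)
        factors.append(
            LandTypeFactor(land, float(row.equivalence_factor), float(row.yield_factor))
        )
    return factors


def load_yield_table(path: str | Path | None = None) -> list[ConsumptionItem]:
    """Read a consumption-item yield CSV; ``None`` loads the packaged defaults."""
    if path is None:
        path = resources.files("ecofoot3d.data") / "yields.csv"
    df = pd.read_csv(path)
    if df.empty:
        logger.warning("%s: empty yield table", path)
        return []
    _require_columns(
        df,
        ["item", "land_type", "account", "average_yield",
         "energy_footprint_density", "convert_coefficient"],
        path,
    )

    def _opt(v) -> float | None:
        return None if pd.isna(v) else float(v)

    items = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        name = str(row.item).strip()
        if name in seen:
            raise ValidationError(f"{path}: duplicate item {name!r}")
        seen.add(name)
        items.append(
            ConsumptionItem(
                name=name,
                land_type=parse_land_type(row.land_type),
                account=Account(str(row.account).strip().lower()),
                average_yield=_opt(row.average_yield),
                energy_footprint_density=_opt(row.energy_footprint_density),
                convert_coefficient=_opt(row.convert_coefficient),
                unit=str(getattr(row, "unit", "") or ""),
            )
        )
    return items


def load_city_panel(
    path: str | Path,
    items: Sequence[ConsumptionItem] | None = None,
    per_capita: bool = True,
) -> list[CityYearRecord]:
    """Read a long-format city-year panel CSV into records.

    Consumption columns are ``cons_<item>``, land-area columns
    ``area_<land_type>``; with ``per_capita=False`` city totals are divided
    by population on ingest.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["city", "year", "population", *INDICATOR_NAMES], path)
    if df.duplicated(subset=["city", "year"]).any():
        dup = df[df.duplicated(subset=["city", "year"])].iloc[0]
        raise ValidationError(f"{path}: duplicate (city, year) key ({dup.city}, {dup.year})")

    cons_cols = [c for c in df.columns if c.startswith("cons_")]
    area_cols = [c for c in df.columns if c.startswith("area_")]
    if items is not None:
        known = {it.name for it in items}
        unknown = [c for c in cons_cols if c[len("cons_"):] not in known]
        if unknown:
            raise ValidationError(f"{path}: consumption columns {unknown} not in yield table")

    records = []
    for row in df.itertuples(index=False):
        pop = float(row.population)
        if not pop > 0:
            raise ValidationError(f"{path}: population <= 0 for ({row.city}, {row.year})")
        scale = 1.0 if per_capita else 1.0 / pop
        consumption = {
            c[len("cons_"):]: float(getattr(row, c)) * scale for c in cons_cols
        }
        land_area = {
            parse_land_type(c[len("area_"):]): float(getattr(row, c)) * scale
            for c in area_cols
        }
        records.append(
            CityYearRecord(
                city=str(row.city),
                year=int(row.year),
                population=pop,
                consumption=consumption,
                land_area=land_area,
                indicators=tuple(float(getattr(row, x)) for x in INDICATOR_NAMES),
            )
        )
    return records


def panel_to_frame(records: Sequence[CityYearRecord]) -> pd.DataFrame:
    """Serialize records back to the long-format panel schema."""
    if not records:
        raise ValidationError("cannot serialize an empty panel")
    item_names = sorted({n for r in records for n in r.consumption})
    land_names = sorted({lt.value for r in records for lt in r.land_area})
    rows = []
    for r in records:
        row: dict[str, object] = {"city": r.city, "year": r.year, "population": r.population}
        for n in item_names:
            row[f"cons_{n}"] = r.consumption.get(n, 0.0)
        for n in land_names:
            row[f"area_{n}"] = r.land_area.get(LandType(n), 0.0)
        for name, value in zip(INDICATOR_NAMES, r.indicators):
            row[name] = value
        rows.append(row)
    return pd.DataFrame(rows)


def write_panel(records: Sequence[CityYearRecord], path: str | Path) -> None:
    write_results(panel_to_frame(records), path)


def write_results(records: pd.DataFrame | Sequence, path: str | Path) -> None:
    """Write a result table as CSV with stable column order and full precision."""
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        if not records:
            raise ValidationError("refusing to write an empty result set")
        df = pd.DataFrame([r.as_row() if hasattr(r, "as_row") else r for r in records])
    if df.empty:
        raise ValidationError("refusing to write an empty result set")
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# packaged reference tables (published summary statistics for the Chengdu
# urban agglomeration, 2000-2019)


def load_reference_land_depth() -> pd.DataFrame:
    """Published per-land-type footprint depths for the eight CUA cities."""
    return pd.read_csv(resources.files("ecofoot3d.data") / "cua_land_depth.csv")


def load_reference_ef3d() -> pd.DataFrame:
    """Published per-capita three-dimensional footprints (hm2/cap) of the CUA."""
    return pd.read_csv(resources.files("ecofoot3d.data") / "cua_ef3d_per_capita.csv")


def load_reference_importance() -> pd.DataFrame:
    """Published X1-X9 importance-ratio table (%) with OOB goodness of fit."""
    return pd.read_csv(resources.files("ecofoot3d.data") / "cua_importance_ratios.csv")
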