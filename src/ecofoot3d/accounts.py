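"""Ecological footprint and carrying-capacity accounting.

Per-capita footprint of the biological account is

    ef_j = sum_i r_j * C_i / Y_i          (items i on land type j)

with C_i the per-capita consumption (kg/cap) and Y_i the provincial-hectare
average yield (kg/hm2).  Energy items are converted to area through their low
calorific value: area_i = C_i * q_i / D_i * r_j, with q_i the GJ per declared
unit and D_i the energy-footprint density (GJ/hm2); fossil fuels accumulate
on carbon-capture land, electricity on built-up land.

Per-capita carrying capacity is ec_j = a_j * r_j * y_j * 0.88, the 0.12
deduction being the biodiversity set-aside.  The ecological balance
ED = EF - EC is positive in deficit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .data_io import (
    Account,
    AnalysisConfig,
    CityYearRecord,
    ConsumptionItem,
    LandType,
    LandTypeFactor,
)
from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)


def _factor_map(factors: Sequence[LandTypeFactor]) -> dict[LandType, LandTypeFactor]:
    return {f.land_type: f for f in factors}


def _zero_map() -> dict[LandType, float]:
    return {lt: 0.0 for lt in LandType}


@dataclass(frozen=True)
class FootprintAccount:
    """Per-land-type per-capita footprint and carrying capacity for a city-year."""

    city: str
    year: int
    population: float
    ef_per_capita: Mapping[LandType, float]
    ec_per_capita: Mapping[LandType, float]

    @property
    def ef_total_per_capita(self) -> float:
        return sum(self.ef_per_capita.values())

    @property
    def ec_total_per_capita(self) -> float:
        return sum(self.ec_per_capita.values())

    def total_ef(self) -> float:
        """Aggregate footprint EF = ef * N (hm2)."""
        return self.ef_total_per_capita * self.population

    def total_ec(self) -> float:
        """Aggregate carrying capacity EC = ec * N (hm2)."""
        return self.ec_total_per_capita * self.population

    def as_row(self) -> dict:
        row: dict[str, object] = {"city": self.city, "year": self.year,
                                  "population": self.population}
        for lt in LandType:
            row[f"ef_{lt.value}"] = self.ef_per_capita.get(lt, 0.0)
        for lt in LandType:
            row[f"ec_{lt.value}"] = self.ec_per_capita.get(lt, 0.0)
        row["ef_per_capita"] = self.ef_total_per_capita
        row["ec_per_capita"] = self.ec_total_per_capita
        row["ed_total"] = ecological_balance(self)
        return row


def ef_biological(
    record: CityYearRecord,
    items: Sequence[ConsumptionItem],
    factors: Sequence[LandTypeFactor],
) -> dict[LandType, float]:
    """Per-capita footprint of the biological account by land type (hm2/cap)."""
    fmap = _factor_map(factors)
    by_name = {it.name: it for it in items}
    out = _zero_map()
    for name, cons in record.consumption.items():
        item = by_name.get(name)
        if item is None or item.account is not Account.BIOLOGICAL:
            continue
        if item.average_yield is None or item.average_yield <= 0:
            raise ConfigurationError(f"item {name!r} lacks a positive average yield")
        r = fmap[item.land_type].equivalence_factor
        out[item.land_type] += r * cons / item.average_yield
    return out


def ef_energy(
    record: CityYearRecord,
    items: Sequence[ConsumptionItem],
    factors: Sequence[LandTypeFactor],
) -> dict[LandType, float]:
    """Per-capita footprint of the energy account by land type (hm2/cap)."""
    fmap = _factor_map(factors)
    by_name = {it.name: it for it in items}
    out = _zero_map()
    for name, cons in record.consumption.items():
        item = by_name.get(name)
        if item is None or item.account is not Account.ENERGY:
            continue
        if not item.energy_footprint_density or item.energy_footprint_density <= 0:
            raise ConfigurationError(f"item {name!r} has no positive energy-footprint density")
        r = fmap[item.land_type].equivalence_factor
        out[item.land_type] += cons * item.convert_coefficient / item.energy_footprint_density * r
    return out


def ec_per_capita(
    record: CityYearRecord,
    factors: Sequence[LandTypeFactor],
    retention: float = 0.88,
) -> dict[LandType, float]:
    """Per-capita carrying capacity by land type: a_j * r_j * y_j * retention."""
    if not 0 < retention <= 1:
        raise ValidationError(f"retention must be in (0, 1], got {retention}")
    fmap = _factor_map(factors)
    out = _zero_map()
    for land, area in record.land_area.items():
        if land not in fmap:
            raise ValidationError(f"no factors supplied for land type {land}")
        f = fmap[land]
        out[land] = area * f.equivalence_factor * f.yield_factor * retention
    missing = [lt.value for lt in LandType if lt not in record.land_area]
    if missing:
        logger.debug("%s/%s: no area supplied for %s, carrying capacity 0",
                     record.city, record.year, missing)
    return out


def ecological_balance(account: FootprintAccount) -> float:
    """Ecological profit and loss ED = EF - EC (hm2, total); positive = deficit."""
    return (account.ef_total_per_capita - account.ec_total_per_capita) * account.population


def build_account(
    record: CityYearRecord,
    items: Sequence[ConsumptionItem],
    factors: Sequence[LandTypeFactor],
    retention: float = 0.88,
) -> FootprintAccount:
    """Compose biological and energy footprints with carrying capacity."""
    bio = ef_biological(record, items, factors)
    energy = ef_energy(record, items, factors)
    ef = {lt: bio[lt] + energy[lt] for lt in LandType}
    ec = ec_per_capita(record, factors, retention)
    return FootprintAccount(
        city=record.city,
        year=record.year,
        population=record.population,
        ef_per_capita=ef,
        ec_per_capita=ec,
    )


def build_accounts(
    records: Sequence[CityYearRecord],
    items: Sequence[ConsumptionItem],
    factors: Sequence[LandTypeFactor],
    config: AnalysisConfig | None = None,
) -> list[FootprintAccount]:
    retention = (config or AnalysisConfig()).biodiversity_retention
    return [build_account(r, items, factors, retention) for r in records]
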