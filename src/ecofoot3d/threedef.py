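"""Revised three-dimensional ecological footprint indicators.

The 3D model splits demand on nature into a flow component (footprint size)
and a stock-depletion component (footprint depth):

    EF_size  = sum_j min(EF_j, EC_j)
    EF_depth = 1 + sum_j max(EF_j - EC_j, 0) / sum_j EC_j
    EF_3D    = EF_size * EF_depth

Per-land-type deficits are taken BEFORE summation, so a surplus on one land
type cannot offset a deficit on another (the revision that distinguishes
this from the original formulation, where regional netting understates
depth).  When every land type is in surplus the depth stays at its original
length 1.  Carbon-capture land has zero carrying capacity, hence contributes
its whole footprint to the depth numerator and nothing to size.

Also provides the per-land-type depth, the coefficient of variation used to
compare depth dispersion across cities, and start/end change statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .accounts import FootprintAccount
from .data_io import LandType
from .errors import UndefinedDepthError, ValidationError

#: relative guard for the balance point EF_j = EC_j: deficits this small are
#: float noise from round-tripped inputs, not stock depletion
_BALANCE_RTOL = 1e-12


def _deficit(ef_j: float, ec_j: float) -> float:
    d = ef_j - ec_j
    return d if d > _BALANCE_RTOL * max(ef_j, ec_j) else 0.0


@dataclass(frozen=True)
class ThreeDEFResult:
    """Size, depth and 3D footprint for one city-year.

    ``ef_size``/``ef3d`` are totals (hm2) unless ``per_capita`` is set, in
    which case they are hm2/cap.  ``land_depth`` maps each land type to its
    own depth; NaN marks the undefined case (no carrying capacity but a
    positive footprint, e.g. carbon-capture land).
    """

    city: str
    year: int
    ef_size: float
    ef_depth: float
    ef3d: float
    land_depth: Mapping[LandType, float]
    per_capita: bool = False

    def as_row(self) -> dict:
        row: dict[str, object] = {
            "city": self.city,
            "year": self.year,
            "ef_size": self.ef_size,
            "ef_depth": self.ef_depth,
            "ef3d": self.ef3d,
            "per_capita": self.per_capita,
        }
        for lt in LandType:
            row[f"depth_{lt.value}"] = self.land_depth.get(lt, float("nan"))
        return row


def ef_size(account: FootprintAccount) -> float:
    """Footprint size: the part of demand met by natural capital flow (hm2)."""
    n = account.population
    return sum(
        min(account.ef_per_capita.get(lt, 0.0), account.ec_per_capita.get(lt, 0.0))
        for lt in LandType
    ) * n


def ef_depth(account: FootprintAccount) -> float:
    """Footprint depth: layers of annual regeneration consumed (dimensionless >= 1)."""
    ef = account.ef_per_capita
    ec = account.ec_per_capita
    total_ec = sum(ec.values())
    if total_ec <= 0:
        raise UndefinedDepthError(
            f"{account.city}/{account.year}: depth undefined, total carrying capacity is 0"
        )
    deficit = sum(_deficit(ef.get(lt, 0.0), ec.get(lt, 0.0)) for lt in LandType)
    return 1.0 + deficit / total_ec


def land_depth(ef_j: float, ec_j: float) -> float:
    """Single-land-type depth: max(1, EF_j/EC_j); NaN when EC_j = 0 < EF_j."""
    if ef_j < 0 or ec_j < 0:
        raise ValidationError("land_depth requires non-negative inputs")
    if ec_j > 0:
        ratio = ef_j / ec_j
        return ratio if ratio > 1.0 + _BALANCE_RTOL else 1.0
    return 1.0 if ef_j == 0 else float("nan")


def ef3d(size: float, depth: float) -> float:
    """Three-dimensional footprint: size x depth (hm2)."""
    if size < 0:
        raise ValidationError(f"size must be >= 0, got {size}")
    if depth < 1:
        raise ValidationError(f"depth must be >= 1, got {depth}")
    return size * depth


def compute_threedef(account: FootprintAccount, per_capita: bool = False) -> ThreeDEFResult:
    """Full 3D result for one account; ``per_capita`` divides size/3D by N."""
    size = ef_size(account)
    depth = ef_depth(account)
    if per_capita:
        size = size / account.population
    depths = {
        lt: land_depth(account.ef_per_capita.get(lt, 0.0), account.ec_per_capita.get(lt, 0.0))
        for lt in LandType
    }
    return ThreeDEFResult(
        city=account.city,
        year=account.year,
        ef_size=size,
        ef_depth=depth,
        ef3d=ef3d(size, depth),
        land_depth=depths,
        per_capita=per_capita,
    )


def compute_panel_threedef(
    accounts: Sequence[FootprintAccount], per_capita: bool = False
) -> list[ThreeDEFResult]:
    return [compute_threedef(a, per_capita) for a in accounts]


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample coefficient of variation in percent: 100 * sd(n-1) / mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValidationError("coefficient of variation needs at least two values")
    mean = arr.mean()
    if mean == 0:
        raise ValidationError("coefficient of variation undefined for zero mean")
    return 100.0 * arr.std(ddof=1) / mean


class ChangeStats(NamedTuple):
    absolute: float
    percent: float
    annualized: float


def change_stats(start: float, end: float, years: int) -> ChangeStats:
    """Absolute change, percent change, and geometric annualized rate (%).

    The ratio outputs are NaN when ``start <= 0``; the absolute change is
    always defined.
    """
    if years < 1:
        raise ValidationError(f"years must be >= 1, got {years}")
    absolute = end - start
    if start <= 0:
        return ChangeStats(absolute, float("nan"), float("nan"))
    percent = 100.0 * absolute / start
    annualized = 100.0 * ((end / start) ** (1.0 / years) - 1.0)
    return ChangeStats(absolute, percent, annualized)


def land_depth_table(results: Sequence[ThreeDEFResult]):
    """Wide city x land-type depth matrix (one row per city-year)."""
    import pandas as pd

    rows = []
    for r in results:
        row: dict[str, object] = {"city": r.city, "year": r.year}
        for lt in LandType:
            row[lt.value] = r.land_depth.get(lt, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)


def change_table(results: Sequence[ThreeDEFResult]):
    """Per-city EF3D change statistics between the first and last panel years."""
    import pandas as pd

    by_city: dict[str, dict[int, float]] = {}
    for r in results:
        by_city.setdefault(r.city, {})[r.year] = r.ef3d
    rows = []
    for city, series in by_city.items():
        years = sorted(series)
        start_y, end_y = years[0], years[-1]
        stats = change_stats(series[start_y], series[end_y], max(end_y - start_y, 1))
        rows.append(
            {
                "city": city,
                "start_year": start_y,
                "end_year": end_y,
                "ef3d_start": series[start_y],
                "ef3d_end": series[end_y],
                "change_abs": stats.absolute,
                "change_pct": stats.percent,
                "annualized_pct": stats.annualized,
            }
        )
    return pd.DataFrame(rows)
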