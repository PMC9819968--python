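import pytest

from ecofoot3d import (
    CityYearRecord,
    LandType,
    load_factor_table,
    load_yield_table,
)


@pytest.fixture(scope="session")
def factors():
    return load_factor_table()


@pytest.fixture(scope="session")
def items():
    return load_yield_table()


@pytest.fixture(scope="session")
def factor_map(factors):
    return {f.land_type: f for f in factors}


@pytest.fixture(scope="session")
def item_map(items):
    return {it.name: it for it in items}


def make_record(
    consumption=None,
    land_area=None,
    city="TestCity",
    year=2000,
    population=1_000_000.0,
    indicators=None,
):
    return CityYearRecord(
        city=city,
        year=year,
        population=population,
        consumption=consumption or {},
        land_area=land_area or {},
        indicators=tuple(indicators) if indicators is not None else tuple(range(1, 10)),
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def grain_record():
    """Single-item record: 545.3472 kg/cap of grain, 0.1 hm2/cap of cropland."""
    return make_record(
        consumption={"grain": 545.3472},
        land_area={LandType.CROPLANDS: 0.1},
    )
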