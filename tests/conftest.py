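import pytest

from evcost import (
    Benchmark,
    Catalog,
    Category,
    FacilityRecord,
    ServiceType,
    paper_fixture,
)


@pytest.fixture(scope="session")
def fixture():
    """Packaged 17-center study tables and derived aggregates."""
    return paper_fixture()


@pytest.fixture(scope="session")
def catalog(fixture):
    return fixture.catalog


def make_tiny_catalog(benchmark_minutes: float = 15.0) -> Catalog:
    """Two-stratum, three-service catalog for hand-checkable arithmetic."""
    return Catalog(
        benchmark=Benchmark(workload=benchmark_minutes),
        strata=("urban", "suburban"),
        services=(
            ServiceType(
                id="visit",
                name="Clinic visit",
                category=Category.BASIC_MEDICAL,
                workload={"urban": benchmark_minutes, "suburban": benchmark_minutes},
            ),
            ServiceType(
                id="home_visit",
                name="Home visit",
                category=Category.BASIC_MEDICAL,
                workload={"urban": 60.0, "suburban": 60.0},
            ),
            ServiceType(
                id="records",
                name="Records management",
                category=Category.NEPHSP,
                in_nephsp=True,
                workload={"urban": 30.0, "suburban": 45.0},
            ),
        ),
    )


def make_facility(
    fid="f1",
    stratum="urban",
    population=10_000.0,
    hr=600.0,
    materials=100.0,
    public=300.0,
    volumes=None,
) -> FacilityRecord:
    return FacilityRecord(
        id=fid,
        stratum=stratum,
        population_served=population,
        expenditure={"human_resources": hr, "materials": materials, "public_funds": public},
        volumes=volumes or {},
    )


@pytest.fixture()
def tiny_catalog():
    return make_tiny_catalog()


@pytest.fixture()
def tiny_panel(tiny_catalog):
    """Two facilities, hand-computable EVs: urban 100x1 + 50x4 + 20x2 = 340."""
    facs = [
        make_facility(
            "u1", "urban", 10_000, 600, 100, 300,
            volumes={"visit": 100, "home_visit": 50, "records": 20},
        ),
        make_facility(
            "s1", "suburban", 5_000, 300, 50, 150,
            volumes={"visit": 40, "records": 10},
        ),
    ]
    return tiny_catalog, facs
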