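"""Synthetic panels with planted ground truth, and the packaged study fixture.

Two jobs live here.

:func:`generate` builds a random but fully controlled world: a catalog of
services with per-stratum workloads, and a panel of facility-year records
whose expenditures are *constructed* from a planted cost-per-EV — for each
facility, total expenditure = c* x measured EV / (1 - uplift) — so that
full-precision costing must recover c* exactly.  Volumes are log-normal per
service (larger centers deliver proportionally more) and rescaled so category
workload shares follow the observed profile of a real urban/suburban panel.

:func:`paper_fixture` loads the packaged encodings of the 2010 Beijing
17-center study tables: the 27-service catalog with urban/suburban workload
indicators, stratum-level expenditure by input category with populations, and
stratum-level measured EV by service category.  Values are stored
digit-for-digit as printed; aggregates are derived from them by the package's
own rules (10% uplift, half-up integer EV totals).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .catalog import (
    Benchmark,
    Catalog,
    Category,
    MEASURED_CATEGORIES,
    ServiceType,
)
from .errors import DomainError
from .facility import (
    EXPENDITURE_CATEGORIES,
    POOLED_LABEL,
    FacilityRecord,
    StratumAggregate,
)
from .rounding import round_half_up, to_decimal

__all__ = ["SyntheticConfig", "generate", "PaperFixture", "paper_fixture",
           "TOTAL_POPULATION_SERVED"]

#: Total population served by the 17 sampled centers as used in the study's
#: per-capita division.  (The source prints both 1,296,403 and 1,296,408, and
#: the stratum averages imply 1,296,409; 1,296,408 is the divisor that the
#: published per-capita figures chain from.)
TOTAL_POPULATION_SERVED = 1_296_408

# Observed category shares of measured (pre-uplift) workload, pooled over the
# study panel; used only to shape synthetic volumes realistically.
_CATEGORY_EV_SHARES = {
    Category.BASIC_MEDICAL: 0.3566,
    Category.NURSING: 0.0425,
    Category.PHARMACY: 0.1016,
    Category.AUXILIARY_EXAM: 0.0634,
    Category.NEPHSP: 0.4359,
}


class SyntheticConfig(BaseModel):
    """Knobs of the synthetic world; defaults mirror the study's setting."""

    model_config = ConfigDict(frozen=True)

    seed: int = 0
    n_facilities_by_stratum: dict[str, int] = Field(
        default_factory=lambda: {"urban": 7, "suburban": 10}
    )
    n_services_by_category: dict[Category, int] = Field(
        default_factory=lambda: {
            Category.BASIC_MEDICAL: 5,
            Category.NURSING: 5,
            Category.PHARMACY: 2,
            Category.AUXILIARY_EXAM: 5,
            Category.NEPHSP: 10,
        }
    )
    workload_range: tuple[float, float] = (4.0, 1200.0)  # person-minutes
    volume_sigma: float = 1.0  # log-normal shape of per-service volumes
    category_ev_shares: dict[Category, float] = Field(
        default_factory=lambda: dict(_CATEGORY_EV_SHARES)
    )
    planted_cost_per_ev: dict[str, float] = Field(
        default_factory=lambda: {"urban": 1.71, "suburban": 2.05}
    )
    expenditure_category_shares: dict[str, float] = Field(
        default_factory=lambda: {
            "human_resources": 0.66,
            "materials": 0.10,
            "public_funds": 0.24,
        }
    )
    population_range: tuple[int, int] = (30_000, 160_000)  # persons
    uplift_share: float = 0.10

    @model_validator(mode="after")
    def _feasible(self) -> "SyntheticConfig":
        if not self.n_facilities_by_stratum or any(
            n < 1 for n in self.n_facilities_by_stratum.values()
        ):
            raise DomainError("need at least one facility per declared stratum")
        if not self.n_services_by_category or any(
            n < 1 for n in self.n_services_by_category.values()
        ):
            raise DomainError("need at least one service per declared category")
        lo, hi = self.workload_range
        if not (0 < lo <= hi):
            raise DomainError(f"invalid workload_range {self.workload_range}")
        lo, hi = self.population_range
        if not (0 < lo <= hi):
            raise DomainError(f"invalid population_range {self.population_range}")
        if not np.isclose(sum(self.expenditure_category_shares.values()), 1.0):
            raise DomainError("expenditure_category_shares must sum to 1")
        if set(self.expenditure_category_shares) != set(EXPENDITURE_CATEGORIES):
            raise DomainError("expenditure shares must cover exactly the three categories")
        if set(self.planted_cost_per_ev) != set(self.n_facilities_by_stratum):
            raise DomainError("planted_cost_per_ev must cover exactly the strata")
        if not 0 <= self.uplift_share < 1:
            raise DomainError(f"uplift_share must be in [0, 1), got {self.uplift_share}")
        return self


def generate(config: SyntheticConfig | None = None) -> tuple[Catalog, list[FacilityRecord]]:
    """Generate a (catalog, facility panel) pair with planted cost-per-EV.

    Reproducible: a fixed seed yields bit-identical output.  Generated panels
    always validate against their catalog, and full-precision costing of the
    panel returns ``config.planted_cost_per_ev`` per stratum exactly (to
    float associativity, well below 1e-9 relative).
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    strata = tuple(config.n_facilities_by_stratum)

    services: list[ServiceType] = []
    for cat, n in config.n_services_by_category.items():
        for i in range(n):
            lo, hi = config.workload_range
            wl = {s: float(np.round(rng.uniform(lo, hi), 2)) for s in strata}
            services.append(
                ServiceType(
                    id=f"{cat.value}_{i:02d}",
                    name=f"Synthetic {cat.value.replace('_', ' ')} service {i}",
                    category=cat,
                    delivery_unit="per unit",
                    in_nephsp=cat is Category.NEPHSP,
                    workload=wl,
                )
            )
    catalog = Catalog(benchmark=Benchmark(), services=tuple(services), strata=strata)

    shares = config.category_ev_shares
    share_total = sum(shares.get(c, 0.0) for c in config.n_services_by_category)

    facilities: list[FacilityRecord] = []
    for stratum in strata:
        n_fac = config.n_facilities_by_stratum[stratum]
        lo, hi = config.population_range
        pops = rng.integers(lo, hi + 1, size=n_fac)
        size_factor = pops / pops.mean()

        # raw log-normal volumes per facility x service, scaled by center size
        raw = {
            s.id: rng.lognormal(mean=np.log(5_000.0), sigma=config.volume_sigma, size=n_fac)
            * size_factor
            for s in services
        }
        # rescale per category so category EV shares match the target profile
        ev_by_cat = {
            cat: sum(
                raw[s.id].sum() * s.workload[stratum] / catalog.benchmark.workload
                for s in services
                if s.category is cat
            )
            for cat in config.n_services_by_category
        }
        grand = sum(ev_by_cat.values())
        volumes_by_service: dict[str, np.ndarray] = {}
        for s in services:
            target = shares.get(s.category, 0.0) / share_total * grand
            factor = target / ev_by_cat[s.category]
            volumes_by_service[s.id] = np.maximum(np.rint(raw[s.id] * factor), 1.0)

        c_star = config.planted_cost_per_ev[stratum]
        hr_share = config.expenditure_category_shares["human_resources"]
        mat_share = config.expenditure_category_shares["materials"]
        for j in range(n_fac):
            vols = {s.id: float(volumes_by_service[s.id][j]) for s in services}
            measured_ev = sum(
                vols[s.id] * s.workload[stratum] / catalog.benchmark.workload
                for s in services
            )
            total_exp = c_star * measured_ev / (1.0 - config.uplift_share)
            hr = total_exp * hr_share
            mat = total_exp * mat_share
            facilities.append(
                FacilityRecord(
                    id=f"{stratum}_{j:02d}",
                    stratum=stratum,
                    population_served=float(pops[j]),
                    n_employees=int(rng.integers(60, 200)),
                    expenditure={
                        "human_resources": hr,
                        "materials": mat,
                        "public_funds": total_exp - hr - mat,
                    },
                    volumes=vols,
                )
            )
    return catalog, facilities


# -- packaged study fixture ---------------------------------------------------


@dataclass(frozen=True)
class PaperFixture:
    """The packaged study tables plus aggregates derived from them."""

    catalog: Catalog
    aggregates: dict[str, StratumAggregate]
    populations: dict[str, float]
    expenditures: pd.DataFrame  # printed expenditure table, digit-for-digit


def _data(name: str) -> pd.DataFrame:
    with resources.files("evcost.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def load_fixture_catalog() -> Catalog:
    """The 27-service urban/suburban catalog with the 15-minute benchmark."""
    from .catalog import load_catalog

    with resources.as_file(
        resources.files("evcost.data").joinpath("catalog_beijing2010.csv")
    ) as p:
        return load_catalog(p)


def paper_fixture(uplift_share: float = 0.10) -> PaperFixture:
    """Catalog, stratum aggregates, populations and expenditures of the study.

    Stratum populations are average population x center count (only averages
    were published); the pooled population is the published total divisor
    (:data:`TOTAL_POPULATION_SERVED`).  The pooled aggregate uses the printed
    pooled expenditure cells and the sum of the stratum category EVs, with
    the uplift applied once; EV totals are rounded half-up to whole EVs.
    """
    catalog = load_fixture_catalog()
    exp = _data("stratum_expenditure.csv").set_index("stratum")
    evs = _data("stratum_category_ev.csv")

    populations: dict[str, float] = {}
    aggregates: dict[str, StratumAggregate] = {}
    for stratum in ("urban", "suburban", POOLED_LABEL):
        row = exp.loc[stratum]
        n_fac = int(row["n_facilities"])
        if stratum == POOLED_LABEL:
            population = float(TOTAL_POPULATION_SERVED)
            by_cat = {
                c: float(evs.loc[evs["category"] == c.value, "measured_ev"].sum())
                for c in MEASURED_CATEGORIES
            }
        else:
            population = float(row["avg_population_served"]) * n_fac
            sub = evs[evs["stratum"] == stratum].set_index("category")
            by_cat = {c: float(sub.loc[c.value, "measured_ev"]) for c in MEASURED_CATEGORIES}
        measured = sum(by_cat.values())
        total_ev = float(
            round_half_up(to_decimal(measured) / (1 - to_decimal(uplift_share)), 0)
        )
        populations[stratum] = population
        aggregates[stratum] = StratumAggregate(
            stratum=stratum,
            n_facilities=n_fac,
            population=population,
            expenditure={c: float(row["exp_" + c]) for c in EXPENDITURE_CATEGORIES},
            measured_ev_by_category=by_cat,
            measured_ev_total=measured,
            total_ev=total_ev,
            uplift_share=uplift_share,
        )
    return PaperFixture(
        catalog=catalog,
        aggregates=aggregates,
        populations=populations,
        expenditures=exp.reset_index(),
    )
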