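"""Facility-year records and their aggregation into strata.

A :class:`FacilityRecord` is one community health center for one year:
population served (residents of at least 6 months), annual expenditure split
into the three government input categories (human resources, materials,
public funds; USD), and annual service volumes keyed by catalog service id.

:func:`aggregate` pools facilities per stratum, converts volumes to EV via the
catalog, and applies the *other-services uplift*: services too heterogeneous
to enumerate are taken to account for a fixed share ``u`` of total workload
(10% by default, from provider group interviews), so

    total EV = measured EV / (1 - u).

The uplift is applied once per aggregate, never per facility.  EV totals are
rounded half-up to whole EVs when ``round_totals`` is true (the published
reporting convention) and kept at full precision otherwise — full precision
is what makes planted-cost recovery on synthetic panels exact.

File formats: a facility CSV
``facility_id,stratum,population_served,n_employees,exp_human_resources,exp_materials,exp_public_funds``
paired with a long-format volume CSV ``facility_id,service_id,volume``; or a
single JSON file nesting volumes per facility.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .catalog import Catalog, Category, MEASURED_CATEGORIES
from .errors import DomainError, EVCostError, SchemaError
from .rounding import round_half_up, to_decimal

__all__ = [
    "EXPENDITURE_CATEGORIES",
    "POOLED_LABEL",
    "FacilityRecord",
    "StratumAggregate",
    "load_facilities",
    "save_facilities",
    "validate_against_catalog",
    "aggregate",
]

#: Government input-cost taxonomy for facility expenditure.
EXPENDITURE_CATEGORIES: tuple[str, ...] = ("human_resources", "materials", "public_funds")

#: Scope label of the pooled (all-strata) aggregate.
POOLED_LABEL = "all"


class FacilityRecord(BaseModel):
    """One center-year of population, expenditure and service volumes."""

    model_config = ConfigDict(frozen=True)

    id: str
    stratum: str
    population_served: float = Field(gt=0)
    expenditure: dict[str, float]
    volumes: dict[str, float] = Field(default_factory=dict)
    n_employees: int | None = None

    @field_validator("expenditure")
    @classmethod
    def _expenditure_complete(cls, v: dict[str, float]) -> dict[str, float]:
        missing = [c for c in EXPENDITURE_CATEGORIES if c not in v]
        if missing:
            raise SchemaError("missing expenditure categories", missing)
        unknown = [c for c in v if c not in EXPENDITURE_CATEGORIES]
        if unknown:
            raise SchemaError("unknown expenditure categories", unknown)
        neg = {c: x for c, x in v.items() if x < 0}
        if neg:
            raise DomainError(f"negative expenditure {neg}")
        return v

    @field_validator("volumes")
    @classmethod
    def _volumes_nonnegative(cls, v: dict[str, float]) -> dict[str, float]:
        neg = {s: x for s, x in v.items() if x < 0}
        if neg:
            raise DomainError(f"negative volumes {neg}")
        return v

    @property
    def expenditure_total(self) -> float:
        return sum(self.expenditure.values())


class StratumAggregate(BaseModel):
    """Pooled expenditure, measured EV by category, uplifted total EV, population."""

    model_config = ConfigDict(frozen=True)

    stratum: str
    n_facilities: int = Field(ge=1)
    population: float = Field(gt=0)
    expenditure: dict[str, float]
    measured_ev_by_category: dict[Category, float]
    measured_ev_total: float
    total_ev: float
    uplift_share: float = 0.10
    measured_ev_by_service: dict[str, float] | None = None

    @model_validator(mode="after")
    def _consistent(self) -> "StratumAggregate":
        s = sum(
            v for c, v in self.measured_ev_by_category.items() if c is not Category.OTHER
        )
        if not math.isclose(s, self.measured_ev_total, rel_tol=1e-9, abs_tol=1e-6):
            raise DomainError(
                f"{self.stratum}: measured_ev_total {self.measured_ev_total} != "
                f"category sum {s}"
            )
        if self.total_ev + 0.5 < self.measured_ev_total:  # allow integer rounding slack
            raise DomainError(
                f"{self.stratum}: total_ev {self.total_ev} < measured {self.measured_ev_total}"
            )
        return self

    @property
    def expenditure_total(self) -> float:
        return sum(self.expenditure.values())


# -- I/O ---------------------------------------------------------------------

_FAC_COLS = [
    "facility_id",
    "stratum",
    "population_served",
    "n_employees",
    "exp_human_resources",
    "exp_materials",
    "exp_public_funds",
]


def load_facilities(
    path: str | Path,
    volumes_path: str | Path | None = None,
    fmt: str | None = None,
) -> list[FacilityRecord]:
    """Load facility records from a CSV pair or a single JSON file."""
    path = Path(path)
    fmt = fmt or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "json":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        return [FacilityRecord.model_validate(r) for r in raw["facilities"]]

    df = pd.read_csv(path, dtype={"facility_id": str}, float_precision="round_trip")
    missing = [c for c in _FAC_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"facility file {path} is missing columns", missing)
    if df.empty:
        raise SchemaError(f"facility file {path} contains no records")

    volumes: dict[str, dict[str, float]] = {}
    if volumes_path is not None:
        vdf = pd.read_csv(
            volumes_path,
            dtype={"facility_id": str, "service_id": str},
            float_precision="round_trip",
        )
        vmissing = [c for c in ("facility_id", "service_id", "volume") if c not in vdf.columns]
        if vmissing:
            raise SchemaError(f"volume file {volumes_path} is missing columns", vmissing)
        for rec in vdf.to_dict("records"):
            volumes.setdefault(rec["facility_id"], {})[rec["service_id"]] = float(rec["volume"])

    problems: list[str] = []
    out: list[FacilityRecord] = []
    for row_no, rec in enumerate(df.to_dict("records"), start=2):
        fid = str(rec["facility_id"])
        try:
            n_emp = rec.get("n_employees")
            out.append(
                FacilityRecord(
                    id=fid,
                    stratum=str(rec["stratum"]),
                    population_served=float(rec["population_served"]),
                    n_employees=None if pd.isna(n_emp) else int(n_emp),
                    expenditure={
                        c: float(rec["exp_" + c]) for c in EXPENDITURE_CATEGORIES
                    },
                    volumes=volumes.get(fid, {}),
                )
            )
        except (EVCostError, ValueError, KeyError) as exc:
            problems.append(f"line {row_no} (facility {fid!r}): {exc}")
    if problems:
        raise SchemaError(f"invalid rows in facility file {path}", problems)
    return out


def save_facilities(
    facilities: Sequence[FacilityRecord],
    path: str | Path,
    volumes_path: str | Path | None = None,
    fmt: str | None = None,
) -> None:
    """Inverse of :func:`load_facilities` (CSV pair or single JSON)."""
    path = Path(path)
    fmt = fmt or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "json":
        payload = {"facilities": [f.model_dump(mode="json") for f in facilities]}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return
    rows = [
        {
            "facility_id": f.id,
            "stratum": f.stratum,
            "population_served": repr(f.population_served),
            "n_employees": "" if f.n_employees is None else f.n_employees,
            **{"exp_" + c: repr(f.expenditure[c]) for c in EXPENDITURE_CATEGORIES},
        }
        for f in facilities
    ]
    pd.DataFrame(rows, columns=_FAC_COLS).to_csv(path, index=False)
    if volumes_path is not None:
        vrows = [
            {"facility_id": f.id, "service_id": sid, "volume": repr(vol)}
            for f in facilities
            for sid, vol in f.volumes.items()
        ]
        pd.DataFrame(vrows, columns=["facility_id", "service_id", "volume"]).to_csv(
            volumes_path, index=False
        )


# -- validation & aggregation ------------------------------------------------


def validate_against_catalog(
    facilities: Iterable[FacilityRecord], catalog: Catalog
) -> None:
    """Raise :class:`SchemaError` if any record references an unknown service or stratum."""
    known = set(catalog.ids)
    strata = set(catalog.strata)
    problems: list[str] = []
    for f in facilities:
        if f.stratum not in strata:
            problems.append(f"facility {f.id!r}: unknown stratum {f.stratum!r}")
        for sid in f.volumes:
            if sid not in known:
                problems.append(f"facility {f.id!r}: volume for unknown service {sid!r}")
    if problems:
        raise SchemaError("facility records inconsistent with catalog", problems)


def _uplifted_total(measured: float, uplift_share: float, round_totals: bool) -> float:
    total = to_decimal(measured) / (1 - to_decimal(uplift_share))
    return float(round_half_up(total, 0)) if round_totals else float(total)


def aggregate(
    facilities: Sequence[FacilityRecord],
    catalog: Catalog,
    uplift_share: float = 0.10,
    *,
    round_totals: bool = True,
) -> dict[str, StratumAggregate]:
    """Pool facilities into per-stratum aggregates plus a pooled ``"all"`` entry.

    Measured EV per category is the sum over facilities and services of
    volume x EV(service, stratum).  The pooled aggregate sums the per-stratum
    measured EVs and applies the uplift once.
    """
    facilities = list(facilities)
    if not facilities:
        raise DomainError("cannot aggregate an empty facility set")
    if not 0 <= uplift_share < 1:
        raise DomainError(f"uplift_share must be in [0, 1), got {uplift_share}")
    validate_against_catalog(facilities, catalog)

    out: dict[str, StratumAggregate] = {}
    strata_present = [s for s in catalog.strata if any(f.stratum == s for f in facilities)]
    for stratum in strata_present:
        members = [f for f in facilities if f.stratum == stratum]
        by_cat: dict[Category, float] = {c: 0.0 for c in MEASURED_CATEGORIES}
        by_service: dict[str, float] = {}
        for f in members:
            for sid, vol in f.volumes.items():
                svc = catalog.service(sid)
                ev = vol * catalog.ev(sid, stratum)
                by_cat[svc.category] = by_cat.get(svc.category, 0.0) + ev
                by_service[sid] = by_service.get(sid, 0.0) + ev
        measured = sum(by_cat.values())
        out[stratum] = StratumAggregate(
            stratum=stratum,
            n_facilities=len(members),
            population=sum(f.population_served for f in members),
            expenditure={
                c: sum(f.expenditure[c] for f in members) for c in EXPENDITURE_CATEGORIES
            },
            measured_ev_by_category=by_cat,
            measured_ev_total=measured,
            total_ev=_uplifted_total(measured, uplift_share, round_totals),
            uplift_share=uplift_share,
            measured_ev_by_service=by_service,
        )

    pooled_by_cat: dict[Category, float] = {c: 0.0 for c in MEASURED_CATEGORIES}
    pooled_by_service: dict[str, float] = {}
    for agg in out.values():
        for c, v in agg.measured_ev_by_category.items():
            pooled_by_cat[c] = pooled_by_cat.get(c, 0.0) + v
        for sid, v in (agg.measured_ev_by_service or {}).items():
            pooled_by_service[sid] = pooled_by_service.get(sid, 0.0) + v
    pooled_measured = sum(pooled_by_cat.values())
    out[POOLED_LABEL] = StratumAggregate(
        stratum=POOLED_LABEL,
        n_facilities=len(facilities),
        population=sum(f.population_served for f in facilities),
        expenditure={
            c: sum(f.expenditure[c] for f in facilities) for c in EXPENDITURE_CATEGORIES
        },
        measured_ev_by_category=pooled_by_cat,
        measured_ev_total=pooled_measured,
        total_ev=_uplifted_total(pooled_measured, uplift_share, round_totals),
        uplift_share=uplift_share,
        measured_ev_by_service=pooled_by_service,
    )
    return out
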