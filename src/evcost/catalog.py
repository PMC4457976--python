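"""Service catalog: taxonomy, benchmark visit, and equivalent values (EV).

Every primary-health-care service is characterised by a *workload indicator*:
the staff person-minutes needed to deliver one unit of the service in a given
stratum (delivery context, e.g. urban vs suburban).  Workloads are normalised
to a common currency by dividing by the workload of a *benchmark* service —
a standard 15-minute family-physician clinic visit — giving the service's
dimensionless equivalent value (EV).  A 60-minute home visit thus has EV 4.

EVs are kept at full precision everywhere; rounding to two decimals is a
display concern handled by the reporting policy in :mod:`evcost.costing`.

File formats
------------
CSV: ``service_id,name,category,delivery_unit,in_nephsp,workload_<stratum>``
(one workload column per stratum; stratum order = column order).  The CSV
form carries no benchmark and loads with the default 15-minute benchmark.
JSON mirrors the full model including a ``benchmark`` object.
"""

from __future__ import annotations

import json
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .errors import DomainError, EVCostError, SchemaError

__all__ = [
    "Category",
    "MEASURED_CATEGORIES",
    "Benchmark",
    "ServiceType",
    "Catalog",
    "compute_ev",
    "ev_table",
    "load_catalog",
    "save_catalog",
]


class Category(str, Enum):
    """Closed service-category vocabulary (the costing tables' rows)."""

    BASIC_MEDICAL = "basic_medical"
    NURSING = "nursing"
    PHARMACY = "pharmacy"
    AUXILIARY_EXAM = "auxiliary_exam"
    NEPHSP = "nephsp"
    OTHER = "other"


#: Categories whose workload is measured from recorded volumes.  "other" is
#: never stored with volumes; it enters totals through the uplift rule.
MEASURED_CATEGORIES: tuple[Category, ...] = (
    Category.BASIC_MEDICAL,
    Category.NURSING,
    Category.PHARMACY,
    Category.AUXILIARY_EXAM,
    Category.NEPHSP,
)


class Benchmark(BaseModel):
    """The service defining one EV: a standard clinic visit of 15 person-minutes."""

    model_config = ConfigDict(frozen=True)

    workload: float = Field(default=15.0, description="person-minutes per unit")
    label: str = "standard clinic visit"

    @field_validator("workload")
    @classmethod
    def _positive(cls, v: float) -> float:
        if not v > 0:
            raise DomainError(f"benchmark workload must be > 0, got {v}")
        return v


class ServiceType(BaseModel):
    """One catalog entry with per-stratum workload indicators.

    ``workload`` maps stratum label -> person-minutes per delivery unit.
    ``in_nephsp`` is redundant with ``category == nephsp`` and validated so.
    """

    model_config = ConfigDict(frozen=True)

    id: str
    name: str
    category: Category
    delivery_unit: str = "per unit"
    in_nephsp: bool = False
    workload: dict[str, float]

    @field_validator("workload")
    @classmethod
    def _positive_workloads(cls, v: dict[str, float], info) -> dict[str, float]:
        bad = {k: w for k, w in v.items() if not w > 0}
        if bad:
            raise DomainError(f"non-positive workload(s) {bad}")
        return v

    @model_validator(mode="after")
    def _nephsp_flag_consistent(self) -> "ServiceType":
        if self.in_nephsp != (self.category is Category.NEPHSP):
            raise DomainError(
                f"service {self.id!r}: in_nephsp={self.in_nephsp} inconsistent "
                f"with category={self.category.value!r}"
            )
        return self


class Catalog(BaseModel):
    """A benchmark, an ordered list of strata, and the service taxonomy."""

    model_config = ConfigDict(frozen=True)

    benchmark: Benchmark = Benchmark()
    services: tuple[ServiceType, ...]
    strata: tuple[str, ...]

    @model_validator(mode="after")
    def _consistent(self) -> "Catalog":
        if not self.strata:
            raise SchemaError("catalog must declare at least one stratum")
        if len(set(self.strata)) != len(self.strata):
            raise SchemaError(f"duplicate stratum labels: {list(self.strata)}")
        seen: set[str] = set()
        dupes: list[str] = []
        for s in self.services:
            if s.id in seen:
                dupes.append(s.id)
            seen.add(s.id)
        if dupes:
            raise SchemaError("duplicate service ids", sorted(set(dupes)))
        want = set(self.strata)
        bad = [s.id for s in self.services if set(s.workload) != want]
        if bad:
            raise SchemaError(
                f"services whose workload map does not cover strata {sorted(want)}",
                bad,
            )
        return self

    # -- lookups -------------------------------------------------------------

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.services)

    def service(self, service_id: str) -> ServiceType:
        for s in self.services:
            if s.id == service_id:
                return s
        raise KeyError(f"unknown service id {service_id!r}")

    def services_in(self, category: Category | str) -> tuple[ServiceType, ...]:
        category = Category(category)
        return tuple(s for s in self.services if s.category is category)

    def ev(self, service_id: str, stratum: str) -> float:
        """EV of one unit of ``service_id`` delivered in ``stratum``."""
        s = self.service(service_id)
        try:
            w = s.workload[stratum]
        except KeyError:
            raise KeyError(f"service {service_id!r} has no workload for stratum {stratum!r}")
        return compute_ev(w, self.benchmark, service_id=service_id)

    def resolve_program(self, program: Category | str | Iterable[str]) -> tuple[str, ...]:
        """Expand a program selector (a category or explicit service ids) to ids."""
        if isinstance(program, (Category,)) or (
            isinstance(program, str) and program in Category._value2member_map_
        ):
            ids = tuple(s.id for s in self.services_in(Category(program)))
        elif isinstance(program, str):
            ids = (program,)
        else:
            ids = tuple(program)
        if not ids:
            raise DomainError(f"program selector {program!r} resolves to no services")
        known = set(self.ids)
        missing = [i for i in ids if i not in known]
        if missing:
            raise SchemaError("program references unknown service ids", missing)
        return ids


def compute_ev(workload: float, benchmark: Benchmark, service_id: str | None = None) -> float:
    """EV of a workload indicator: ``workload / benchmark.workload``, unrounded."""
    who = f" for service {service_id!r}" if service_id else ""
    if not workload > 0:
        raise DomainError(f"workload must be > 0{who}, got {workload}")
    if not benchmark.workload > 0:  # unreachable through the model, kept for raw use
        raise DomainError(f"benchmark workload must be > 0, got {benchmark.workload}")
    return workload / benchmark.workload


def ev_table(catalog: Catalog) -> dict[tuple[str, str], float]:
    """Full-precision EV per (service id, stratum)."""
    return {
        (s.id, stratum): compute_ev(s.workload[stratum], catalog.benchmark, s.id)
        for s in catalog.services
        for stratum in catalog.strata
    }


# -- I/O ---------------------------------------------------------------------

_WL_PREFIX = "workload_"
_CSV_FIXED = ["service_id", "name", "category", "delivery_unit", "in_nephsp"]


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt
    return "json" if path.suffix.lower() == ".json" else "csv"


def load_catalog(path: str | Path, fmt: str | None = None) -> Catalog:
    """Load and validate a catalog from CSV or JSON (inferred from suffix)."""
    path = Path(path)
    if _infer_format(path, fmt) == "json":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        return Catalog.model_validate(raw)

    df = pd.read_csv(path, dtype={"service_id": str}, float_precision="round_trip")
    missing = [c for c in _CSV_FIXED if c not in df.columns]
    if missing:
        raise SchemaError(f"catalog file {path} is missing columns", missing)
    wl_cols = [c for c in df.columns if c.startswith(_WL_PREFIX)]
    if not wl_cols:
        raise SchemaError(f"catalog file {path} has no workload_<stratum> column")
    if df.empty:
        raise SchemaError(f"catalog file {path} contains no services")
    strata = tuple(c[len(_WL_PREFIX):] for c in wl_cols)

    problems: list[str] = []
    services: list[ServiceType] = []
    for row_no, rec in enumerate(df.to_dict("records"), start=2):  # header = line 1
        try:
            services.append(
                ServiceType(
                    id=str(rec["service_id"]),
                    name=str(rec["name"]),
                    category=str(rec["category"]),
                    delivery_unit=str(rec["delivery_unit"]),
                    in_nephsp=_parse_bool(rec["in_nephsp"]),
                    workload={s: float(rec[_WL_PREFIX + s]) for s in strata},
                )
            )
        except (EVCostError, ValueError, KeyError) as exc:
            problems.append(f"line {row_no}: {exc}")
    if problems:
        raise SchemaError(f"invalid rows in catalog file {path}", problems)
    return Catalog(services=tuple(services), strata=strata)


def _parse_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    s = str(v).strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no"}:
        return False
    raise ValueError(f"cannot parse boolean {v!r}")


def save_catalog(catalog: Catalog, path: str | Path, fmt: str | None = None) -> None:
    """Write a catalog; ``load_catalog`` of the result reproduces it."""
    path = Path(path)
    if _infer_format(path, fmt) == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(catalog.model_dump(mode="json"), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return
    rows = [
        {
            "service_id": s.id,
            "name": s.name,
            "category": s.category.value,
            "delivery_unit": s.delivery_unit,
            "in_nephsp": s.in_nephsp,
            **{_WL_PREFIX + st: repr(s.workload[st]) for st in catalog.strata},
        }
        for s in catalog.services
    ]
    cols = _CSV_FIXED + [_WL_PREFIX + st for st in catalog.strata]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
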