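"""Scenario repricing: the dynamic cost-estimate mechanism.

A :class:`Scenario` is a declarative perturbation of the costing inputs —
salary/price inflation as expenditure multipliers, demand change as volume
multipliers, revised workload indicators, newly added package services with
their expected volumes, a changed allocation, population growth.  Applying a
scenario is a pure transformation ``(facilities, catalog) -> (facilities',
catalog')``; rerunning the costing engine on the result reprices the package
under the new conditions.

The other-services uplift share is *not* a scenario field: it came from
provider group interviews, not from any quantity a scenario perturbs, so it
is held fixed unless the caller overrides it at costing time.

Scenario files are YAML or JSON with keys ``expenditure_multipliers``,
``volume_multipliers`` (keyed by service id or category; a specific id wins
over its category), ``workload_overrides`` (service id -> stratum ->
person-minutes), ``added_services`` (each a service definition plus expected
volume per stratum), ``allocation_per_capita`` and ``population_multiplier``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .catalog import Catalog, Category, ServiceType
from .costing import CostReport
from .errors import DomainError, SchemaError
from .facility import EXPENDITURE_CATEGORIES, FacilityRecord

__all__ = [
    "AddedService",
    "Scenario",
    "load_scenario",
    "apply_scenario",
    "incremental_program_cost",
]


class AddedService(BaseModel):
    """A new catalog entry and its expected annual volume per stratum."""

    model_config = ConfigDict(frozen=True)

    service: ServiceType
    volume_by_stratum: dict[str, float] = Field(default_factory=dict)

    @field_validator("volume_by_stratum")
    @classmethod
    def _nonnegative(cls, v: dict[str, float]) -> dict[str, float]:
        neg = {k: x for k, x in v.items() if x < 0}
        if neg:
            raise DomainError(f"negative expected volumes {neg}")
        return v


class Scenario(BaseModel):
    """Multiplicative/additive perturbations of the costing inputs."""

    model_config = ConfigDict(frozen=True)

    name: str = "scenario"
    expenditure_multipliers: dict[str, float] = Field(default_factory=dict)
    volume_multipliers: dict[str, float] = Field(default_factory=dict)
    workload_overrides: dict[str, dict[str, float]] = Field(default_factory=dict)
    added_services: tuple[AddedService, ...] = ()
    allocation_per_capita: float | None = None
    population_multiplier: float = 1.0

    @field_validator("expenditure_multipliers", "volume_multipliers")
    @classmethod
    def _positive_factors(cls, v: dict[str, float]) -> dict[str, float]:
        bad = {k: f for k, f in v.items() if not f > 0}
        if bad:
            raise DomainError(f"multipliers must be > 0: {bad}")
        return v

    @field_validator("population_multiplier")
    @classmethod
    def _positive_pop(cls, v: float) -> float:
        if not v > 0:
            raise DomainError(f"population_multiplier must be > 0, got {v}")
        return v

    @field_validator("workload_overrides")
    @classmethod
    def _positive_overrides(cls, v: dict[str, dict[str, float]]) -> dict[str, dict[str, float]]:
        bad = [
            f"{sid}/{st}={w}" for sid, m in v.items() for st, w in m.items() if not w > 0
        ]
        if bad:
            raise DomainError(f"workload overrides must be > 0: {bad}")
        return v

    def compose(self, other: "Scenario") -> "Scenario":
        """Scenario equivalent to applying ``self`` then ``other``.

        Multiplicative fields multiply; ``other``'s overrides, added services
        and allocation take precedence.
        """
        exp = dict(self.expenditure_multipliers)
        for k, f in other.expenditure_multipliers.items():
            exp[k] = exp.get(k, 1.0) * f
        vol = dict(self.volume_multipliers)
        for k, f in other.volume_multipliers.items():
            vol[k] = vol.get(k, 1.0) * f
        overrides = {sid: dict(m) for sid, m in self.workload_overrides.items()}
        for sid, m in other.workload_overrides.items():
            overrides.setdefault(sid, {}).update(m)
        return Scenario(
            name=f"{self.name}+{other.name}",
            expenditure_multipliers=exp,
            volume_multipliers=vol,
            workload_overrides=overrides,
            added_services=self.added_services + other.added_services,
            allocation_per_capita=(
                other.allocation_per_capita
                if other.allocation_per_capita is not None
                else self.allocation_per_capita
            ),
            population_multiplier=self.population_multiplier * other.population_multiplier,
        )


def load_scenario(path: str | Path) -> Scenario:
    """Load a scenario from YAML or JSON."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
    if raw is None:
        raw = {}
    return Scenario.model_validate(raw)


def _volume_factor(svc: ServiceType, multipliers: dict[str, float]) -> float:
    if svc.id in multipliers:
        return multipliers[svc.id]
    return multipliers.get(svc.category.value, 1.0)


def apply_scenario(
    facilities: Sequence[FacilityRecord],
    catalog: Catalog,
    scenario: Scenario,
) -> tuple[list[FacilityRecord], Catalog]:
    """Reprice inputs under a scenario; the originals are left untouched."""
    ids = set(catalog.ids)
    unknown = [sid for sid in scenario.workload_overrides if sid not in ids]
    if unknown:
        raise SchemaError("workload overrides for unknown services", unknown)
    clash = [a.service.id for a in scenario.added_services if a.service.id in ids]
    if clash:
        raise SchemaError("added services already present in catalog", clash)
    cats = set(Category._value2member_map_)
    unknown_vm = [
        k for k in scenario.volume_multipliers if k not in ids and k not in cats
    ]
    if unknown_vm:
        raise SchemaError("volume multipliers for unknown services/categories", unknown_vm)

    new_services: list[ServiceType] = []
    for svc in catalog.services:
        if svc.id in scenario.workload_overrides:
            wl = dict(svc.workload)
            wl.update(scenario.workload_overrides[svc.id])
            svc = svc.model_copy(update={"workload": wl})
        new_services.append(svc)
    for added in scenario.added_services:
        new_services.append(added.service)
    new_catalog = Catalog(
        benchmark=catalog.benchmark,
        services=tuple(new_services),
        strata=catalog.strata,
    )

    # expected volumes of added services are split across a stratum's
    # facilities proportionally to population served
    pop_by_stratum: dict[str, float] = {}
    for f in facilities:
        pop_by_stratum[f.stratum] = pop_by_stratum.get(f.stratum, 0.0) + f.population_served

    new_facilities: list[FacilityRecord] = []
    for f in facilities:
        volumes = {
            sid: vol * _volume_factor(catalog.service(sid), scenario.volume_multipliers)
            for sid, vol in f.volumes.items()
        }
        for added in scenario.added_services:
            total = added.volume_by_stratum.get(f.stratum, 0.0)
            if total:
                volumes[added.service.id] = (
                    total * f.population_served / pop_by_stratum[f.stratum]
                )
        expenditure = {
            c: f.expenditure[c] * scenario.expenditure_multipliers.get(c, 1.0)
            for c in EXPENDITURE_CATEGORIES
        }
        new_facilities.append(
            f.model_copy(
                update={
                    "volumes": volumes,
                    "expenditure": expenditure,
                    "population_served": f.population_served
                    * scenario.population_multiplier,
                }
            )
        )
    return new_facilities, new_catalog


def incremental_program_cost(base: CostReport, scenario_report: CostReport) -> dict[str, float]:
    """Field-wise differences (scenario minus base) for a shared scope."""
    if base.scope != scenario_report.scope:
        raise DomainError(
            f"scope mismatch: base {base.scope!r} vs scenario {scenario_report.scope!r}"
        )
    deltas = {
        "program_ev": scenario_report.program_ev - base.program_ev,
        "program_cost": scenario_report.program_cost - base.program_cost,
        "cost_per_ev_total": scenario_report.cost_per_ev_total - base.cost_per_ev_total,
        "cost_per_capita_total": scenario_report.cost_per_capita_total
        - base.cost_per_capita_total,
    }
    if (
        base.funding_gap_per_capita is not None
        and scenario_report.funding_gap_per_capita is not None
    ):
        deltas["funding_gap_per_capita"] = (
            scenario_report.funding_gap_per_capita - base.funding_gap_per_capita
        )
    return deltas
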