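"""Scenario repricing: purity, composition, added services, deltas."""

import pytest

from evcost import (
    Category,
    DomainError,
    FULL_PRECISION,
    PAPER,
    Scenario,
    SchemaError,
    ServiceType,
    SyntheticConfig,
    apply_scenario,
    full_report,
    generate,
    incremental_program_cost,
    load_scenario,
)
from evcost.scenario import AddedService


@pytest.fixture(scope="module")
def panel():
    return generate(SyntheticConfig(seed=21))


def test_identity_scenario_is_fixed_point(panel):
    cat, facs = panel
    facs2, cat2 = apply_scenario(facs, cat, Scenario())
    assert cat2 == cat
    assert full_report(facs2, cat2, policy=PAPER) == full_report(facs, cat, policy=PAPER)


def test_inputs_not_mutated(panel):
    cat, facs = panel
    before = [f.model_copy(deep=True) for f in facs]
    apply_scenario(
        facs, cat, Scenario(expenditure_multipliers={"materials": 2.0})
    )
    assert facs == before


def test_expenditure_multiplier_scales_cost_per_ev(panel):
    """x1.10 on every input category -> cost/EV x1.10 at full precision."""
    cat, facs = panel
    scen = Scenario(
        expenditure_multipliers={
            "human_resources": 1.10, "materials": 1.10, "public_funds": 1.10
        }
    )
    facs2, cat2 = apply_scenario(facs, cat, scen)
    base = full_report(facs, cat, policy=FULL_PRECISION)
    after = full_report(facs2, cat2, policy=FULL_PRECISION)
    for scope in base:
        assert after[scope].cost_per_ev_total == pytest.approx(
            1.10 * base[scope].cost_per_ev_total, rel=1e-9
        )


def test_volume_multiplier_category_vs_service_precedence(panel):
    cat, facs = panel
    sid = cat.services_in(Category.NEPHSP)[0].id
    scen = Scenario(volume_multipliers={"nephsp": 2.0, sid: 3.0})
    facs2, _ = apply_scenario(facs, cat, scen)
    f0, f0b = facs[0], facs2[0]
    assert f0b.volumes[sid] == pytest.approx(3.0 * f0.volumes[sid])
    other = cat.services_in(Category.NEPHSP)[1].id
    assert f0b.volumes[other] == pytest.approx(2.0 * f0.volumes[other])
    basic = cat.services_in(Category.BASIC_MEDICAL)[0].id
    assert f0b.volumes[basic] == pytest.approx(f0.volumes[basic])


def _added(volume_urban=900.0, volume_suburban=600.0, workload=30.0):
    return AddedService(
        service=ServiceType(
            id="new_screening",
            name="New screening program",
            category=Category.NEPHSP,
            in_nephsp=True,
            workload={"urban": workload, "suburban": workload},
        ),
        volume_by_stratum={"urban": volume_urban, "suburban": volume_suburban},
    )


def test_added_service_increases_program_ev_by_volume_times_ev(panel):
    """A 30-minute service has EV 2; total volume V adds exactly 2V EV."""
    cat, facs = panel
    scen = Scenario(added_services=(_added(900.0, 600.0),))
    facs2, cat2 = apply_scenario(facs, cat, scen)
    base = full_report(facs, cat, policy=FULL_PRECISION)
    after = full_report(facs2, cat2, policy=FULL_PRECISION)
    assert after["urban"].program_ev - base["urban"].program_ev == pytest.approx(
        2 * 900.0, rel=1e-9
    )
    assert after["all"].program_ev - base["all"].program_ev == pytest.approx(
        2 * 1500.0, rel=1e-9
    )
    # distributed proportionally to population within each stratum
    urban = [f for f in facs2 if f.stratum == "urban"]
    pops = [f.population_served for f in urban]
    vols = [f.volumes["new_screening"] for f in urban]
    assert sum(vols) == pytest.approx(900.0, rel=1e-12)
    ratio = vols[0] / pops[0]
    assert all(v / p == pytest.approx(ratio, rel=1e-9) for v, p in zip(vols, pops))


def test_added_service_with_zero_volume_changes_nothing(panel):
    cat, facs = panel
    scen = Scenario(added_services=(_added(0.0, 0.0),))
    facs2, cat2 = apply_scenario(facs, cat, scen)
    assert full_report(facs2, cat2, policy=PAPER) == full_report(facs, cat, policy=PAPER)


def test_composition_of_multiplicative_scenarios(panel):
    cat, facs = panel
    s1 = Scenario(
        name="a",
        expenditure_multipliers={"materials": 1.5},
        volume_multipliers={"nursing": 2.0},
        population_multiplier=1.1,
    )
    s2 = Scenario(
        name="b",
        expenditure_multipliers={"materials": 1.2, "public_funds": 0.9},
        volume_multipliers={"nursing": 0.5},
        population_multiplier=1.2,
    )
    seq_f, seq_c = apply_scenario(*apply_scenario(facs, cat, s1), s2)
    comp_f, comp_c = apply_scenario(facs, cat, s1.compose(s2))
    assert seq_c == comp_c
    for a, b in zip(seq_f, comp_f):
        assert a.population_served == pytest.approx(b.population_served, rel=1e-12)
        for c in a.expenditure:
            assert a.expenditure[c] == pytest.approx(b.expenditure[c], rel=1e-12)
        for s in a.volumes:
            assert a.volumes[s] == pytest.approx(b.volumes[s], rel=1e-12)


def test_workload_override_changes_ev(panel):
    cat, facs = panel
    sid = cat.services[0].id
    scen = Scenario(workload_overrides={sid: {"urban": 150.0}})
    _, cat2 = apply_scenario(facs, cat, scen)
    assert cat2.ev(sid, "urban") == pytest.approx(10.0)
    assert cat2.ev(sid, "suburban") == cat.ev(sid, "suburban")


def test_scenario_validation(panel):
    cat, facs = panel
    with pytest.raises(SchemaError, match="ghost"):
        apply_scenario(facs, cat, Scenario(workload_overrides={"ghost": {"urban": 5.0}}))
    with pytest.raises(SchemaError, match="already present"):
        dup = AddedService(
            service=cat.services[0], volume_by_stratum={"urban": 1.0}
        )
        apply_scenario(facs, cat, Scenario(added_services=(dup,)))
    with pytest.raises(DomainError):
        Scenario(expenditure_multipliers={"materials": 0.0})


def test_incremental_cost_zero_for_identical_reports(panel):
    cat, facs = panel
    rep = full_report(facs, cat, policy=PAPER, allocation=3.97)
    deltas = incremental_program_cost(rep["all"], rep["all"])
    assert set(deltas.values()) == {0.0}


def test_incremental_cost_allocation_change(panel):
    """Raising the allocation from 2.38 to 3.97 narrows the gap by 1.59."""
    cat, facs = panel
    low = full_report(facs, cat, policy=PAPER, allocation=2.38)
    high = full_report(facs, cat, policy=PAPER, allocation=3.97)
    deltas = incremental_program_cost(low["all"], high["all"])
    assert deltas["funding_gap_per_capita"] == pytest.approx(-1.59)
    assert deltas["program_cost"] == 0.0


def test_incremental_cost_scope_mismatch(panel):
    cat, facs = panel
    rep = full_report(facs, cat, policy=PAPER)
    with pytest.raises(DomainError, match="scope mismatch"):
        incremental_program_cost(rep["urban"], rep["all"])


def test_added_service_delta_cost_closed_form(panel):
    """delta program cost = (added EV) x new cost/EV at full precision."""
    cat, facs = panel
    scen = Scenario(added_services=(_added(900.0, 600.0),))
    facs2, cat2 = apply_scenario(facs, cat, scen)
    base = full_report(facs, cat, policy=FULL_PRECISION)
    after = full_report(facs2, cat2, policy=FULL_PRECISION)
    d = incremental_program_cost(base["all"], after["all"])
    cpe2 = after["all"].cost_per_ev_total
    expected = (base["all"].program_ev + 3000.0) * cpe2 - base["all"].program_cost
    assert d["program_cost"] == pytest.approx(expected, rel=1e-9)


def test_load_scenario_yaml_and_json(tmp_path):
    y = tmp_path / "s.yaml"
    y.write_text(
        "name: inflation\n"
        "expenditure_multipliers:\n  human_resources: 1.25\n"
        "volume_multipliers:\n  nephsp: 1.1\n"
        "allocation_per_capita: 3.97\n"
    )
    s = load_scenario(y)
    assert s.expenditure_multipliers["human_resources"] == 1.25
    assert s.allocation_per_capita == 3.97
    j = tmp_path / "s.json"
    j.write_text('{"name": "x", "population_multiplier": 1.05}\n')
    assert load_scenario(j).population_multiplier == 1.05
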