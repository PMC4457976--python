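"""Brute-force first-principles costing, independent of the package internals.

Straight-line loops over facilities and services; no aggregation helpers, no
reporting policy, no rounding.  Used to cross-check ``full_report`` in
full-precision mode on small panels.
"""


def brute_force_report(facilities, catalog, program_ids, uplift_share):
    """Return {scope: {...}} computed naively; scopes are strata plus 'all'."""
    bench = catalog.benchmark.workload
    workload = {s.id: s.workload for s in catalog.services}
    out = {}
    strata = [st for st in catalog.strata if any(f.stratum == st for f in facilities)]
    for scope in strata + ["all"]:
        members = [f for f in facilities if scope == "all" or f.stratum == scope]
        expenditure = 0.0
        for f in members:
            for v in f.expenditure.values():
                expenditure += v
        measured = 0.0
        prog = 0.0
        for f in members:
            for sid, vol in f.volumes.items():
                ev = vol * workload[sid][f.stratum] / bench
                measured += ev
                if sid in program_ids:
                    prog += ev
        total_ev = measured / (1.0 - uplift_share)
        cpe = expenditure / total_ev
        cost = prog * cpe
        population = sum(f.population_served for f in members)
        out[scope] = {
            "total_ev": total_ev,
            "cost_per_ev_total": cpe,
            "program_ev": prog,
            "program_share": 100.0 * prog / total_ev,
            "program_cost": cost,
            "cost_per_capita_total": cost / population,
            "population": population,
        }
    return out
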