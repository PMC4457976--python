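# evcost

Workload **equivalent-value (EV) costing** of primary-health-care service
packages.

Primary-care facilities deliver dozens of heterogeneous services — clinic
visits, home visits, immunization sessions, chronic-disease follow-up,
center-level health-education programs — through shared staff, which makes
classic department-based (step-down) costing unusable.  `evcost` implements
the workload-normalization alternative: every service is assigned a
*workload indicator* `w_s` (staff person-minutes per delivery unit, set per
delivery stratum, e.g. urban vs suburban), and is expressed in units of a
benchmark **standard clinic visit** of `w_0 = 15` person-minutes:

```
EV_s = w_s / w_0                      (a 60-minute home visit has EV 4)
```

Annual facility volumes `V_s` then aggregate into a single workload total.
Unenumerated residual services are handled by an *uplift*: they are assumed
to account for a share `u` (default 10%) of total workload, so

```
total EV = ( Σ_s V_s · EV_s ) / (1 − u)
cost per EV = total expenditure / total EV        [USD per standard visit]
```

A program (for example the ten-service National Essential Public Health
Services Package, NEPHSP) is costed as its EV times the cost per EV, divided
by the population served for a per-capita figure, and compared with the
per-capita government allocation to obtain the funding gap.  The unit cost
decomposes additively by input category (human resources, materials, public
funds), and a scenario layer reprices the whole model under changed
salaries, prices, volumes, workload indicators, populations or newly added
services.

The package ships the stratum-level tables of the 2010 Beijing 17-center
NEPHSP costing study as its reference fixture, and a synthetic generator
that builds facility panels with a *planted* cost-per-EV for exact
end-to-end verification.

## Worked example

Cost the packaged Beijing tables under the published reporting convention
(half-up rounding, rounded intermediates), with the 2011 allocation of
3.97 USD per capita:

```
$ evcost cost --fixtures --policy paper --allocation 3.97 --format table
Cost of one EV (USD)
                 urban  suburban  all
Human Resources   1.12      1.38 1.24
Materials         0.14      0.23 0.18
Public Funds      0.45      0.44 0.45
Total             1.71      2.05 1.87

Program cost per capita (USD)
                 urban  suburban  all
Human Resources   4.79      5.82 5.27
Materials         0.60      0.97 0.77
Public Funds      1.92      1.86 1.91
Total             7.31      8.65 7.95
```

Reading the pooled column: the 17 centers delivered 14,056,402
standard-visit equivalents on 26.3 M USD of expenditure, so one standard
clinic visit costs **1.87 USD** (1.24 of it staff cost).  The NEPHSP program
is 5,514,777 EV — 39.23% of the total workload — costing 10,312,633 USD,
i.e. **7.95 USD per person** served; against a 3.97 USD allocation the
per-capita funding gap is 3.98 USD.  The same command with `--format json`
emits the full machine-readable report (`program_ev`, `program_share`,
`funding_gap_per_capita`, ...).

The same pipeline runs on your own data:

```
evcost validate --catalog catalog.csv --facilities facilities.csv --volumes volumes.csv
evcost cost     --catalog catalog.csv --facilities facilities.csv --volumes volumes.csv \
                --policy paper --program nephsp --allocation 3.97
evcost scenario --scenario inflation.yaml --catalog ... --facilities ... --volumes ...
evcost generate --seed 7 --out-dir demo/        # synthetic panel with known truth
evcost fixtures export --out-dir fixtures/      # the packaged study tables
```

Library use mirrors the CLI: `evcost.load_catalog`, `evcost.load_facilities`,
`evcost.full_report`, `evcost.apply_scenario`, `evcost.generate`,
`evcost.paper_fixture`.

## Acceptance script

`scripts/acceptance.py` re-runs the two end-to-end pipelines from scratch —
the packaged-study cost report under the paper reporting policy, and a
seeded synthetic panel whose planted cost-per-EV must be recovered to
1e-9 relative — and writes the results JSON:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/evcost/catalog.py` — service taxonomy, benchmark, EV computation, catalog I/O
- `src/evcost/facility.py` — facility-year records, stratum aggregation, the uplift rule
- `src/evcost/costing.py` — cost per EV, program cost, per-capita cost, funding gap
- `src/evcost/scenario.py` — scenario repricing (the dynamic cost-estimate mechanism)
- `src/evcost/synthetic.py` — synthetic panels with planted truth; packaged study fixture
- `src/evcost/cli.py` — `evcost` command-line interface
- `docs/methods.md` — model assumptions, rounding policy, numerical choices, limitations
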