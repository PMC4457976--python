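# Methods

## Model

`evcost` implements an activity-based costing model for primary health care
in which staff time is the single normalizing resource.  Each service `s`
carries a stratum-specific *workload indicator* `w_s(r)` in person-minutes
per delivery unit (per visit, per person-year, per test, per center …).
Dividing by the benchmark workload `w_0` — a standard clinic visit, one
family physician with one patient for 15 minutes — gives the service's
equivalent value `EV_s(r) = w_s(r) / w_0`, a dimensionless exchange rate
between services.  EVs are linear in workload and equal 1 for the benchmark
by construction.

For a set of facilities in stratum `r` with annual volumes `V_fs`:

- measured workload: `M_r = Σ_f Σ_s V_fs · EV_s(r)`
- uplifted total:    `T_r = M_r / (1 − u)`
- unit cost:         `c_r = E_r / T_r`, with `E_r` total annual expenditure
- program cost:      `C_r = P_r · c_r`, with `P_r` the program's summed EV
- per capita:        `C_r / N_r`, with `N_r` the population served
- funding gap:       per-capita cost − per-capita allocation.

The unit cost decomposes by input category (human resources, materials,
public funds) because expenditure does; at full precision the category
components sum exactly to the total (conservation), and the model is
homogeneous: scaling expenditure by k scales costs by k, scaling volumes by
k scales workloads by k and the unit cost by 1/k.

### Assumptions

- Staff person-minutes are the only cost driver differentiating services;
  capital, equipment intensity and case-mix within a service type are not
  modeled.  Workload indicators come from protocols, not observed practice,
  so the resulting cost is normative rather than observed.
- The uplift share `u` treats residual, unenumerable services as a fixed
  fraction of *total* workload (`other = measured/(1−u) − measured =
  measured · u/(1−u)`; at u = 0.10, one ninth of the measured sum).  It is
  applied once per aggregate, never per facility, and is an interview-derived
  constant — scenario repricing deliberately holds it fixed.
- Strata are free-form labels; each carries its own workload indicators,
  facilities and population.  The packaged fixture defines `urban` and
  `suburban`, reflecting different population density and delivery models,
  but nothing limits the count.

## Tunable parameters

| parameter | unit | default | why |
|---|---|---|---|
| benchmark workload `w_0` | person-minutes | 15 | definition of the standard clinic visit |
| uplift share `u` | fraction of total workload | 0.10 | provider group-interview estimate for residual services |
| program selector | category or service ids | `nephsp` | the ten-service essential package |
| allocation | USD/person/year | none (2.38 in 2009, 3.97 in 2011 as reference points) | government funding benchmark for the gap |
| money decimals | digits | 2 | USD cents |

## Reporting policies and rounding

Two policies govern every chain:

- **full_precision** — no rounding anywhere.  This is the mode for
  verification: conservation and homogeneity hold to 1e-9 relative, and
  synthetic planted costs are recovered exactly.
- **paper** — the published reporting convention.  All rounding is half-up
  (implemented with `decimal.Decimal` on the shortest float repr, so
  4,087,310.5 → 4,087,311 regardless of binary representation).  EV totals
  round to whole EVs; cost per EV rounds to cents *before* multiplying the
  program EV; the program cost rounds to whole USD *before* the per-capita
  division; shares report to two decimals.  Chaining rounded intermediates
  is what reproduces published tables digit-for-digit; the drift relative to
  full precision is bounded by half of the last rounding step.

Reconstructed stratum EV totals carry an inherent ±1 EV uncertainty when the
inputs are themselves rounded category subtotals (the packaged fixture's
published stratum totals differ by exactly 1 from the rule's output on both
strata; the pooled total matches exactly).  Money results are insensitive to
this ±1 at realistic magnitudes.

Degenerate inputs: zero total EV raises a domain error naming the scope
(division undefined); zero expenditure with positive workload is a valid
zero-cost report; a negative funding gap is reported as-is and means
surplus.  An empty facility set or empty program selector is an error, not
an empty report.

## Synthetic generator

`generate(SyntheticConfig(...))` emulates a stratified facility panel:
7 urban + 10 suburban centers by default, populations uniform in
30,000–160,000 (bracketing the fixture's stratum means of 117,687 and
47,260), a catalog of 5/5/2/5/10 services across the five measured
categories with per-stratum workloads uniform in 4–1200 person-minutes (the
fixture's range excluding per-center outlier rows), and per-service volumes
log-normal (σ = 1) scaled by center size and rescaled so category workload
shares follow the observed pooled profile (≈36/4/10/6/44%).  Expenditure is
*constructed* from a planted unit cost: per facility,
`E_f = c*_r · m_f / (1 − u)`, split 66/10/24% across input categories.
Construction makes full-precision recovery of `c*_r` exact by design, so a
green recovery test establishes the internal consistency of aggregation and
costing — not the realism of the panel.  The generator does not emulate
reporting noise, seasonality, case-mix, income-side accounting or
correlations between expenditure shares and size; conclusions about real
data quality cannot be drawn from synthetic greens.  Facility expenditures
are left at full float precision (not rounded to cents): rounding 17
facility totals would inject up to ~1e-8 relative error into stratum totals
and mask the 1e-9 recovery contract.

The packaged study fixture stores every published cell digit-for-digit in
three CSVs (catalog workloads; stratum expenditures and populations; stratum
measured EVs by category) so it can be reviewed independently of the code.
Published stratum *averages* are converted to totals by multiplying by the
center counts; the pooled population divisor is stored as its own constant
because the source prints slightly inconsistent totals (all candidates give
the same per-capita result at cents precision).  One catalog row's published
EV (urban infectious-disease reporting, 94.24) is inconsistent with its own
published workload (5,913.63 minutes → 394.24); the fixture stores the
workload and derives the EV by rule, flagging the printed value as a
suspected misprint.

## Design choices

- EVs and measured workloads propagate at full precision; all display
  rounding lives in the reporting policy.  Published EV tables are
  themselves workload/15 rounded for display.
- The category vocabulary is a closed six-label set; `other` is realized by
  the uplift rule and never stored with volumes.
- Stratum per-capita chains use the stratum's *rounded* cost per EV
  (consistent with the pooled chain); both rounded and unrounded variants
  reproduce the published stratum per-capita figures.
- Per-category per-capita cells are emitted under the same documented chain
  (program EV × rounded category unit cost → whole USD → per capita);
  row/column totals are the verified quantities, individual published
  category cells are not all reproducible under any single rounding chain.
- Added-service volumes in scenarios are distributed to facilities
  proportionally to population served — the only universal size variable in
  the data model — and a new service's expected volume is always a scenario
  input, never derived.
- Scenario composition is defined so multiplicative fields multiply and the
  second scenario's overrides win; applying `s1` then `s2` equals applying
  `s1.compose(s2)`.

## Limitations

- Deterministic accounting only: no confidence intervals, no statistical
  inference about under-funding, no behavioral demand response.
- No currency conversion; all money is in the input currency (USD in the
  packaged fixture).
- Single-year records; multi-year panels are separate record sets.
- Deriving workload indicators from time-and-motion observation data is out
  of scope; indicators are inputs.
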