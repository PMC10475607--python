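# Methods

## The costing model

costkit implements health-systems-perspective micro-costing of a
multi-phase intervention. A cost ledger holds one row per priced resource
(phase, capital/recurrent class, fixed/variable behavior, unit price,
quantity, useful life, apportionment fraction, minutes of use per patient)
plus four study-level parameters: annual discount rate, patient cohort
size, INR/USD exchange rate, and annual operational minutes of the
facility.

Two costing directions coexist, as is standard:

- **Top-down (financial)**: development, pretest and training lines carry
  administrative expenditure totals; a phase summary sums
  `price x quantity x apportionment`, attaches proportional shares, and
  divides by the cohort for a unit cost.
- **Bottom-up (activity-based)**: each delivery line resolves to a
  per-patient cost. Lines already priced per patient pass through.
  Capital lines are annualized, converted to a per-minute rate over the
  annual operational minutes, and charged by minutes of use per patient.
  Salaried-staff lines are valued at opportunity cost: gross monthly
  salary over monthly working minutes, times contact minutes per patient.

### Annualization

Capital of price P with useful life L years at discount rate r costs
`P / A(r, L)` per year with `A(r, L) = (1 − (1+r)^(−L))/r`, payments in
arrears (`A(0, L) = L`). This is the standard annuity convention in
health-economics guidance; re-discounting the annual stream over the life
recovers P exactly, which is property-tested. The implementation uses
`expm1`/`log1p` so the factor degrades gracefully to L as r → 0. A
straight-line alternative (`P / L`) is available behind a config flag for
comparison and is off by default, since a stated discount rate implies the
annuity method.

### Parameters and defaults

| parameter | default | units | why |
|---|---|---|---|
| discount_rate | 0.03 | /year | HTA reference-case rate used by the study |
| cohort_size | 100 | patients | per-clinic denominator implied by the published unit-cost divisions (1,34,002/1,340; 6,59,444/6,594); the study enrolled 200 across two clinics |
| exchange_rate | 74.0 | INR/USD | consistent with most printed USD cells; the table's own implied rates drift 73.0–74.1, so USD figures are reported but never load-bearing |
| working time | 240 days/yr x 480 min/day, 20 days/month | — | conventional public-facility assumption; the study states none, so every result depending on it is config-sensitive |
| DSA spread | ±20% | — | the study's stated default when explicit resource bounds are unavailable |

### Rounding conventions

Money is exact 2-dp decimal internally (the ledger spans 0.15 INR to
lakh-scale lines); rounding happens only at report boundaries, half-up to
integer INR for reported costs and 2 dp for proportions and USD. Two
conventions are deliberate because they are the only ones that reproduce
every published cell:

- Delivery-panel proportions use the **integer-rounded total** (272, not
  272.15) as denominator, reproducing 27.94/9.56/3.68/58.82/0.06
  simultaneously. A side effect is that these printed shares sum to
  100.06; exact-denominator phase summaries sum to 100 ± 0.05.
- Scenario figures round half-up **once, at the final per-patient value**
  (190.43→190, 176.81→177, 107.1075→107); the cumulative "total with
  training" adds the two already-rounded figures, as the published table
  does (173 + 1206 = 1379).

## Sensitivity analysis

One-way deterministic: each parameter moves alone to its low and high
bound while all else stays at base. Parameters target either a single
delivery component (additive perturbation of that component inside the
total) or the overall package cost (multiplicative factor on the reported
total) — both modes exist because published tornado diagrams mix
component-level and aggregate parameters. Explicit bounds pass through;
otherwise base × (1 ∓ spread). Ranking is by descending exact (pre-
rounding) output range with lexicographic tie-break for determinism. With
a symmetric ±20% spread on an additive component the exact range is
0.4 × the component's base value, which serves as a closed-form oracle.

The study's printed range is 184–326 INR. The upper bound reproduces from
+20% on the overall package cost (272 × 1.2 = 326.4 → 326). The lower
bound 184 is **not** derivable from the ±20% default (272 × 0.8 = 217.6 →
218); it reflects parameter-specific lower bounds that were not published.
costkit therefore ships the ±20% default, accepts explicit bounds (passing
(184, 326) through verbatim), and treats 184 as documentation rather than
a reproducible number.

## Scale-up scenarios

- **Group counseling**: components tied to one counseling contact — staff
  time, capital, the dedicated phone line (102.15 INR on the study
  ledger) — divide by the group size; pamphlets and SMS/calls (170 INR)
  stay per-patient. Cost is strictly decreasing in group size with limit
  equal to the non-shareable pool.
- **Bulk procurement**: the discountable pool shrinks by the discount
  fraction; cost is affine in the discount with slope −170 on the study
  ledger.
- **Integrated training**: per-patient training cost × (1 − discount); the
  discount abstracts the saving from folding sessions into existing
  in-service programs, with no attempt to model session content.
- **Cumulative**: group sharing and bulk discount together, plus the
  discounted training cost for a total per-patient figure.

The component partition (shareable = staff + capital + phone;
discountable = pamphlets + SMS/calls) is the default `ScenarioConfig` and
is fully overridable; it is the unique partition consistent with every
published scenario cell. The group-size grid (5/10/15/20) and discount
grid (10–40%) are configurable.

## Budget impact

Year-by-year projection over a horizon (default 10 years): initial
training in year 1, refreshers every `refresher_interval_years` (training
frequency is an input — operational guidelines set it, the study body does
not), delivery at `annual_patients x unit_delivery_cost` every year. Costs
are booked at year start, so year t discounts by `(1+r)^-(t-1)` and year 1
is undiscounted; whether the study's own ten-year projection discounted at
all is not stated, so the convention here is explicit and the rate
configurable (rate 0 gives nominal sums). Validation is against a
closed-form annuity identity and a brute-force per-year loop; no published
multi-year cells exist to assert against.

## Synthetic data

The generator emulates the resource structure of the study's ledger:
development/training lines with financial totals, and a delivery phase
mixing capital goods (price, useful life, minutes of use), salaried staff
(monthly salary, contact minutes) and per-patient consumables. Prices are
drawn log-uniformly to mimic the sub-rupee-to-lakh span of real cost
tables; apportionment fractions come from {0.25, 0.5, 0.75, 1}; all draws
use numpy's seeded Generator, so ledgers are bit-reproducible per seed.

Ground truth is computed at generation time by deliberately independent
arithmetic — annuity factors from an explicit discount-sum loop rather
than the closed form, staff and scenario values from inline formulas —
and holds exact pre-rounding values. The recovery suite then requires the
pipeline to match to 1e-9 relative error across seeds, plus scenario
monotonicity and the 0.4 × component DSA identity.

What the generator does **not** emulate: measurement noise in interview-
based time estimates, correlated prices, salvage values, demand growth, or
patient outcomes. Passing recovery shows the pipeline's arithmetic is
faithful to the model, not that the model captures any particular
facility's cost structure.

## Problem sizes

Everything is desk-scale: the study ledger has 11 cost-bearing lines, and
the default test suite runs the recovery suite at 100 seeds with ledgers
of ~10 lines each, completing in seconds.

## Known limitations

- The published table's internal inconsistencies are preserved, not
  corrected: the printed development total (6,59,447) exceeds its
  component sum (6,59,444) by 3 INR, and the abstract's development cost
  (6,47,827) is the total minus the pretest row (component sum 6,47,824).
  The ledger stores components; both totals are exposed as views and
  agree with the printed figures within the table's own ±3 INR rounding
  slack. The pretest share computes to 1.76% where the table prints 1.77.
- USD values depend on line-to-line drifting implied exchange rates in
  the source table and are informational only.
- Per-minute costing assumes a single homogeneous operational calendar;
  no equipment-specific depreciation schedules or salvage values.
- The DSA lower bound 184 cannot be reproduced without the unpublished
  parameter-specific bounds (see above).
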