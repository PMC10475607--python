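# costkit

Micro-costing toolkit for facility-based health interventions, built around
the published cost analysis of a tobacco-cessation intervention package
delivered at noncommunicable-disease (NCD) clinics in two districts of
Punjab, India. It is written for health economists and program analysts who
need to take a phase-wise cost ledger — development, pretest, provider
training, service delivery — and turn it into unit costs, sensitivity
ranges, scale-up scenarios and a multi-year budget projection.

## What it computes

**Costing model.** Costs are taken from the health-systems perspective and
combined in two directions: development and training lines are summed
top-down from administrative totals, while the per-patient delivery cost is
built bottom-up from activity-level resources. Capital purchases of price
*P* with useful life *L* years are converted to an equivalent annual cost
with the annuity method at annual discount rate *r* (default 3%):

    annual cost = P / A(r, L),   A(r, L) = (1 − (1+r)^(−L)) / r

then spread over the facility's annual operational minutes and charged per
patient by the minutes of use. Staff time is valued at opportunity cost:
gross monthly salary divided by working minutes per month, times contact
minutes per patient. Shared resources enter via an apportionment fraction.
Unit costs divide phase totals by the patient cohort (100 per clinic in the
study).

**Analyses on top of the ledger**

- one-way deterministic sensitivity analysis (±20% default spread, explicit
  bounds supported) with tornado ranking of the most influential inputs;
- scale-up scenarios: disease-specific group counseling (contact-tied
  components shared across the group), bulk procurement discounts on
  pamphlets/SMS, training integrated into routine in-service programs, and
  the cumulative combination;
- a budget-impact projection of training plus delivery costs over a
  multi-year horizon with present-value discounting.

A synthetic-ledger generator draws randomized multi-phase ledgers with
analytically known ground truth, so the whole pipeline is testable without
any external data.

## Worked example

```python
from costkit import (table2_fixture, unit_delivery_cost, phase_summary,
                     group_counseling_cost, one_way_dsa, DSAParameter)

ledger = table2_fixture()                 # the built-in study ledger
bd = unit_delivery_cost(ledger)
print(bd.total_reported)                  # 272  (INR per patient)
print(group_counseling_cost(bd, 10).per_patient_cost)   # 180
dsa = one_way_dsa(ledger, [DSAParameter("overall package cost")])
print(dsa.entries[0].output_high)         # 326
```

or from the shell (`fixture` is the built-in ledger; any CSV/JSON ledger
path works in its place):

```
$ costkit cost fixture
Cost Components of Intervention                               Cost INR (USD)   Prop. %
--------------------------------------------------------------------------------------
[development phase]
Meetings with civil society (n = 2)                            9396 (126.97)      1.42
Workshop with Program Manager (n = 1)                       491040 (6635.68)     74.46
Meeting with Program Manager (n = 1)                         93795 (1267.50)     14.22
Advocacy Workshop (n = 1)                                     53593 (724.23)      8.13
Cost of doing a pre-test                                      11620 (157.03)      1.76
Total                                                       659444 (8911.41)       100
Unit Cost                                                       6594 (89.11)
--------------------------------------------------------------------------------------
[training phase]
Total Health System Cost of Training of HCP                 134002 (1810.84)    100.00
Total                                                       134002 (1810.84)       100
Unit Cost                                                       1340 (18.11)
--------------------------------------------------------------------------------------
[unit cost of service delivery]
Human Resource                                                     76 (1.03)     27.94
Capital Cost (Building, Furniture, Equipment)                      26 (0.35)      9.56
Pamphlets (IEC)                                                    10 (0.14)      3.68
SMS and Follow-up calls (HR)                                      160 (2.16)     58.82
Dedicated Phone Bill                                             0.15 (0.00)      0.06
Overall Cost                                                      272 (3.68)       100
--------------------------------------------------------------------------------------
```

Reading the delivery panel: serving one patient costs 272 INR, of which
telephonic follow-up (160 INR, 58.82%), staff contact time (76 INR) and
annualized capital (26 INR) dominate. Developing the package cost 6,59,444
INR in total (6,594 per patient of the 100-patient cohort), and training
the providers 1,34,002 INR (1,340 per patient).

Other subcommands: `costkit validate`, `costkit dsa` (tornado table and
optional plot), `costkit scenario --grid` (the full scale-up grid),
`costkit bia --config bia.yaml`, `costkit synth` (synthetic ledger plus
ground truth), `costkit fixture --out ledger.csv`.

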