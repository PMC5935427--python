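# Methods

This package implements subnational health-expenditure accounting in the
System of Health Accounts 2011 (SHA 2011) framework, by the **top-down
method**: Current Health Expenditure (CHE) for a whole province is computed
by scaling yearbook-level financial aggregates with allocation coefficients
estimated from an institution-survey of patient encounters and finance
sheets, and the result is then restricted to a beneficiary subpopulation —
children aged 0–14 inclusive. Every unit of spending is placed on five axes:
provider type, health-care function, financing scheme, ICD-10 disease
chapter, and single-year age bin.

## The accounting model

### Scope

CHE counts final consumption of health goods and services: medical income,
the basic expenditure subsidy, and earmarked project subsidies for curative
and public-health services. Capital formation — construction, equipment,
depreciation — is outside CHE and is never counted, although the finance
sheets carry it.

### Allocation coefficients

Survey microdata yield four proportions (estimated per provider-type
stratum where the stratum was observed, pooled otherwise):

| symbol | formula | meaning |
|---|---|---|
| α_i | 1 − E_POI / E_TOI | curative share of outpatient **income** |
| Υ | 1 − N_POV / N_TOV | curative share of outpatient **visits** |
| α_s | N_MS / (N_MS + N_PHS) | curative share of the basic subsidy (equivalent persons) |
| β | N_IBD / (N_IBD + N_IOV·Κ) | inpatient share of the curative basic subsidy (equivalent workload) |

with E_POI / E_TOI the preventive and total outpatient income in the survey,
N_POV / N_TOV the preventive and total outpatient visits, N_MS the count of
medical-service patients (curative outpatient + inpatient), N_PHS the count
of public-health service users (preventive outpatient + public-health
contacts), N_IBD inpatient bed-days, and N_IOV = N_OV·Υ the curative
outpatient visits at provincial scale (N_OV provincial outpatient visits).

**Κ (kappa)** converts one outpatient visit into bed-day equivalents;
default 0.1, i.e. ten visits weigh as much as one bed-day. The expression
for β can also be read literally as the ratio additionally multiplied by Κ;
that reading caps β at Κ and makes the outpatient side receive ≥ 90 % of the
curative basic subsidy regardless of workload, which contradicts the
equivalent-workload idea, so the share form is the default and the literal
form is available as `inpatient_workload_share(..., scale_by_kappa=True)`.

β uses the provincial bed-day count when available (consistent with N_OV
being provincial), falling back to the survey tally; the choice is recorded
in the coefficient provenance.

N_MS and N_PHS are counted over **all ages** when building the
total-population cube; the children's restriction happens afterwards through
cost shares. Head counts (not weighted contacts) define the equivalent
person.

### Top-down scaling

Per provider stratum, with E_OI / E_II the provincial outpatient / inpatient
income, E_BS the basic subsidy and E_OPS / E_IPS the project subsidies:

    E_OCI = E_OI · α_i                 curative outpatient income
    E_BCS = E_BS · α_s                 curative basic subsidy
    E_OBS = E_BCS · (1 − β)            outpatient basic subsidy
    E_OCS = E_OCI + E_OPS + E_OBS      outpatient curative total
    E_ICS = E_II + E_IPS + E_BCS · β   inpatient curative total

Inpatient income takes no preventive deduction (preventive activity is an
outpatient phenomenon). The remainder E_OI·(1 − α_i) is preventive
outpatient income and E_BS·(1 − α_s) the public-health share of the basic
subsidy; both are booked under the **prevention** function.

**Prevention projects** are valued by comparing each project's income and
expense and taking the larger (`prevention_rule="max"`): when a project
overspends its earmarked income the expense measures consumption, otherwise
the income does. A strict `expense_always` variant is provided.

**Other items** on the finance sheets — assistant services, medicine and
management costs, the superior-institution subsidy, science & education
income, other income — are observed only for surveyed institutions and are
scaled to the province by the stratum income ratio (provincial medical
income / survey medical income). Strata never sampled contribute no such
items; with institution-level items a few percent of CHE this biases
provider shares well below the recovery tolerance.

### Financing schemes

Basic and project subsidies, the superior-institution subsidy and
management overhead → **government**; social insurance, commercial
insurance, donations, science & education income and other income →
**social**; out-of-pocket payments → **household**. Income amounts are
split by the survey payer mix. The scheme assignment of science & education
income, "others" and the overhead items is this package's choice (no
standard assignment exists for them); each is a one-line mapping in
`accounts_engine.py`.

### Disease, age, and the children restriction

Every scaled amount is spread over (disease chapter × age bin × scheme)
cells in proportion to the survey's cost pattern within its own
(stratum × service type) — subsidies over the matching curative pool,
prevention money over the preventive pool, overheads over all services.
Because apportionment is age-resolved, restricting to children is exact:
keep the cells in the children age bins. A coarse variant scales whole
strata by the survey children's cost share instead, for cubes without age
detail and for sensitivity analysis.

The children boundary is **inclusive of 14**. The single-year table columns
are "0-1" … "13-14" (half-open intervals), so age 14 lives in an explicit
overflow bin that is part of all children totals but not a column of the
rendered table.

### Classification

ICD-10 chapters follow the standard letter ranges, with two departures that
match the reporting shape: codes R95–R99 (ill-defined causes of death) are
split out of the symptoms chapter as "Death", and V01–Y98 joins S00–T98
under injury. Records with missing codes are kept (money conservation) in
an explicit "unclassified" class. The GBD broad-cause grouping is
chapter-coarse — infectious, maternal and perinatal chapters → group I,
injury → group III, everything else → group II — so respiratory infections
land in group II through the respiratory chapter; the shipped rules file
(`data/classification_rules.yaml`) lets users rearrange this.

## The synthetic-data generator

Provincial yearbook aggregates and institution-survey microdata of the kind
this method consumes are not public, so the package ships a generator that
emulates the *structure*: cities, ten provider-type strata, institution
finance sheets, ICD-coded encounters. It first creates a complete census —
so provincial aggregates are exact sums and an exact ground-truth cube
exists (`tabulate_truth`, a brute-force enumeration independent of the
engine) — and a multistage sampler then draws the "survey" (cities first,
then institutions within provider strata).

Default conditions (all configurable):

| parameter | default | why |
|---|---|---|
| cities × institutions | 4 × 15 = 60 | reduced-size multistage structure |
| encounters/institution | 2000 (120 000 total) | enough survey support for 1-point share recovery at a 30 % sample |
| children's encounter share | 6.19 % of ages on 0–14 | pins the expected children's cost share |
| preventive visit share | 25 % | Υ ground truth of 0.75 |
| inpatient / public-health share | 8 % / 4 % | outpatient-dominated contact mix |
| costs | log-normal per service type (e.g. inpatient exp(μ)=5200 CNY, σ=0.7) | positive, right-skewed expenditure |
| payer split | Dirichlet around (0.28, 0.04, 0.01, 0.02, 0.65) | out-of-pocket-heavy mix |
| subsidy rates | basic 6 %, project 1.5 % of income | small public top-up |
| Κ | 0.1 | workload equivalence |

The disease case-mix defaults to a respiratory-dominated paediatric-style
chapter distribution; preventive contacts carry codes from the
health-status-factors (Z) range. Public-health contact costs are booked as
prevention-project income on the institution's sheet, not as outpatient
income.

**What the generator does not emulate:** real prevalence or price levels,
institution-level case-mix effects (chapters are i.i.d. across encounters
within an age group), age-dependent costs, multi-year dynamics, and survey
design weights (the sampler records its plan; the estimator pools records
unweighted). Passing tests therefore demonstrate that the estimator
reproduces a known allocation under the stated sampling design — not that
any real province's numbers are correct.

## Numerical choices

* Money is CNY `float64` end to end; USD conversion (default 6.20 CNY/USD)
  and half-up rounding to 2 decimals happen only in the reporting layer, and
  every rendered total is summed before rounding.
* Payer splits must reconcile with the total cost to 1e-6 relative;
  violating rows are rejected with line numbers, and rows read + rows
  rejected always equals the physical row count.
* Division-by-zero in any coefficient raises an estimation error rather than
  defaulting — a silent default would corrupt the accounts invisibly. For
  individual strata without survey support the pooled coefficient is used
  and the fallback is recorded in provenance.
* The cube is a long-format table, so marginal additivity is structural;
  validation enforces cell non-negativity, and the census oracle equivalence
  (engine vs enumeration at a 100 % sample) holds to 1e-9 relative cell-wise.

## Known limitations

* Children-level GBD-group shares carry a sampling error of several points
  at a 30 % institution sample (few child inpatient records per hospital
  stratum under heavy-tailed costs); recovery guarantees are stated for the
  total-population cube.
* Confidence intervals for coefficients and cube cells are out of scope.
* The financing table's source rows sum to the cube total by construction
  here; published tables built from heterogeneous sources need not.
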