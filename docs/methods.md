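# Methods

## Scope and perspectives

The package models one question: what would it have cost — and whom — to
discharge hospitalised periprosthetic joint infection (PJI) patients as soon
as clinically defensible and continue intravenous antibiotics at home with
outpatient clinic monitoring? Costs are tracked in parallel from the
statutory payer's view (DRG case payments, quarterly clinic fees, pharmacy
drug bills) and the provider's view (internal cost accounting per case,
per-visit clinic costs). No clinical outcomes are modelled; the counterfactual
is purely financial.

## Case payment (tariff model)

German DRGs pay a fixed inlier relative weight for any stay between the
lower and upper trimming points (UGVD, OGVD). Each day beyond the OGVD adds
a per-day weight (first surcharge day OGVD + 1); each day short of the UGVD
subtracts one (first discount day UGVD − 1). Euros are weight × base case
value (BBFW, 3231.20 € for 2015). The bundled catalogue covers the six
hip/knee-infection DRGs of the cohort (I01Z, I03B, I04Z, I12A, I12B, I12C);
the catalogue and base rate are ordinary inputs, not constants, because
billed amounts in practice deviate from list arithmetic (see "Fidelity to
the cohort data" below).

Money is `decimal.Decimal` quantized to cents with half-up rounding, applied
once per reported quantity. Per-diem products (days × rate) are rounded after
the single multiplication, not per day; this convention matches every
cent-exact table cell the cohort reproduces. A day-by-day accumulation
oracle (`case_revenue_brute_force`) double-checks the closed form in tests.

## The cohort and the inclusion screen

The analysed cohort is twelve 2015 PJI episodes carried as a bundled CSV:
per case the DRG, stay, actual revenue and cost, the surcharge and ward
per-diems, the simulated dischargeable days, and the outpatient inputs
(drug daily rate, clinic quarters, visit count, regimen class). The
screening funnel (133 candidates, 121 excluded, 12 included) is represented
by a synthetic pool — individual excluded patients' attributes are invented
placeholders; only the per-reason tallies are meaningful, and the data file
is named accordingly. Exclusion criteria apply in a fixed precedence order
(minors, short stays, then the clinical flags) with first-match counting, so
the tally partitions the excluded set exactly.

### Fidelity to the cohort data

Three quantities in the source data are not derivable from catalogue
arithmetic and are therefore carried verbatim as inputs rather than
recomputed:

* per-case **actual revenues** (the inlier revenues imply an effective base
  rate of ≈ 3190.81 € rather than 3231.20 €; `case_revenue` remains available
  as a cross-check with either rate);
* case 01's **surcharge per-diem** (904.74 €, far from the I03B catalogue
  value of 255.26 €) and its implied upper trim point;
* case 07's **visit count** (one visit despite a 15-day, most-expensive-drug
  regimen; no schedule formula reproduces it, so regimen class `other`
  defers to the stored count).

The I03B surcharge per-diem itself is an internal inconsistency of the
source catalogue sheet: 0.079 × 3231.20 = 255.2648, i.e. 255.26 after
rounding, which is also the rate the cohort's I03B cases carry; the package
computes 255.26 throughout.

## Early-discharge simulation

Admission is day 0 and a stay of `los` days ends on day `los`. The earliest
eligible discharge day is the latest of: fifth day after the last operation,
day after the last non-trivial medical intervention (radiology and
laboratory excluded), and the day the wound is documented dry (taken as day
0 when undocumented, making the first two criteria binding). The day is
capped at the actual discharge; saved bed days are the difference.

Payer revenue falls only for stays above the OGVD, by
`min(saved_days, los − OGVD) × surcharge per-diem` — inlier revenue is a
lump sum, so discharging an inlier earlier changes nothing for the payer.
Provider cost falls by `saved_days × ward per-diem` for every case, because
operations, intensive care and other lump costs are booked before the
eligibility day. No cohort case falls below its UGVD after simulated
discharge, so the discount branch is never exercised by the fixture (it is
by synthetic and property tests).

## Outpatient costing

Treatment duration equals the saved bed days. Payer: duration × drug daily
rate (pharmacy tariff), plus a 92 € flat fee per started calendar quarter of
clinic contact. Provider: each monitoring visit costs 75 € (personnel 46 €,
materials 3 €, overhead 26 €) against the flat-fee revenue — a structural
deficit for any case needing more than one visit per quarter. Visit
schedules: three visits per full treatment week for vancomycin-type
(thrice-weekly monitoring) regimens, one visit per started week otherwise;
both formulas are config-overridable and a stored per-case count always wins
for regimen class `other`. Laboratory and radiology during OPAT are carried
as zero-cost (cost-neutral) line items rather than silently omitted.
Transport, physiotherapy and opportunity costs of freed beds are out of
scope by design.

The cohort-level payer OPAT total is the sum of per-case drug bills
(57,395.28 € on the bundled cohort); the drug-only figure quoted alongside
it (56,199.28 €) is that total net of the 1,196 € clinic fees. Both are
emitted because the two framings circulate side by side in practice.

## Ledgers and statistics

Payer: `net_extra_cost = opat_total − ipat_savings`. Provider:
`net_benefit = (cost_reduction − revenue_reduction) + clinic_margin`, with a
second, gross framing `|residual deficit| − |clinic deficit|` that does not
net the inpatient revenue reduction — both are computed and labelled
explicitly rather than choosing one. Summary statistics use the arithmetic
mean, the even-n median as the midpoint of the two central order statistics,
and the min–max range; display rounding is half-up to cents, percentages to
whole percent. Report regeneration is deterministic and byte-identical.

## Synthetic generator

`synthetic_cohort` draws screening pools, cases and clinical timelines from
one seeded `numpy` generator. Defaults mirror the study conditions: 12
cases, stays 19–84 days, ages 63–84, drug daily rates 265–570 €, ward
per-diems 230–306 €, half the cases exceeding their OGVD, exclusion-reason
probabilities equal to the observed funnel proportions (out of 133).
Distributions are uniform over these ranges because the study reports only
ranges and means. Lump costs (surgery, ICU) are attached before the
eligibility day so that simulated savings depend only on the ward per-diem —
the generator's central structural fidelity. `dischargeable_days` is
recomputed from the generated timeline through `earliest_discharge_day`,
closing the loop the fixture cannot test. Quarter counts come from a random
calendar placement of the OPAT interval (at most two quarters for stays
under 90 days).

What the generator does **not** emulate: realistic infection courses,
correlated cost structures, billing anomalies like case 01's non-catalogue
per-diem, or schedule-defying cases like 07. Passing tests on synthetic
cohorts therefore demonstrate accounting-identity correctness and scale
behaviour, not clinical realism.

## Numerical and design choices

* Cent-exact `Decimal` arithmetic end to end; no floats in the accounting
  path (floats appear only inside the random generator before quantization).
* Problem sizes in tests are desk scale (cohorts of 5–300 cases, 100 seeds
  for the identity sweep); the whole suite runs in a few seconds.
* Validation errors name the offending field and row; German decimal commas
  are accepted on read, output is always dot-decimal.
* The even-n median convention and the half-up rounding are load-bearing:
  they are what makes the summary statistics land on the printed cents.

## Known limitations

* The counterfactual assumes early discharge is always clinically realised;
  re-admissions and complications are not modelled.
* Payer drug costs use a single daily rate per case; regimen switches
  mid-course are not representable.
* The provider's "gross" benefit framing mixes a stock (residual deficit)
  with a flow (clinic margin); it is reported because it circulates, not
  because it is the better measure — prefer `net_benefit`.
* The screening pool is synthetic at the individual level; per-reason
  tallies are its only meaningful content.
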