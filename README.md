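# opat-costsim

A desk-scale health-economics model comparing **inpatient** parenteral
antibiotic therapy (IPAT) for periprosthetic joint infections (PJI) with a
simulated **outpatient** regimen (OPAT), from the two perspectives that
matter in the German system: the statutory payer (GKV) and the hospital
provider.

## Who this is for

Health-services researchers and hospital controllers who want a transparent,
tested implementation of German DRG case-payment arithmetic, a counterfactual
early-discharge simulation, and outpatient antibiotic costing — reproducible
to the cent, with a synthetic-cohort generator for testing at arbitrary scale.

## The model

**DRG case payment.** A stay of `VD` days in DRG *g* pays
`revenue = (BR_inlier + max(0, VD − OGVD)·BR_ogvd − max(0, UGVD − VD)·BR_ugvd) × BBFW`,
where UGVD/OGVD are the lower/upper length-of-stay trimming points, the `BR`
are relative weights, and BBFW is the federal base case value (3231.20 € in
2015). The first surcharge day is OGVD + 1; the first discount day UGVD − 1.

**Early-discharge counterfactual.** The earliest safe discharge day is
`max(last_operation + 5, last_intervention + 1, wound_dry_day)`, capped at
the actual discharge. The bed days after that day are the OPAT treatment
duration. Payer savings arise only from forfeited long-stay surcharges
(days above the OGVD, at the surcharge per-diem); provider savings accrue
for every saved day at the ward per-diem, because surgery and intensive-care
lump costs precede eligibility.

**OPAT costing.** Payer: treatment days × drug daily rate, plus a 92 €
quarterly clinic flat fee per started quarter. Provider: 75 € per clinic
visit (personnel 46 + materials 3 + overhead 26) against the flat-fee
revenue. Monitoring visits: 3/week for vancomycin-type regimens, 1/week
otherwise.

**Bottom lines.**
`payer net extra cost = OPAT total − inpatient savings`;
`provider net benefit = (cost reduction − revenue reduction) + clinic margin`.

All money is fixed-point cents (`decimal.Decimal`, half-up rounding).

## Worked example

The bundled cohort is twelve 2015 hip/knee PJI episodes (mean age 72.6
years, mean stay 41 days, 159 simulated dischargeable bed days).

```sh
opat-costsim report --out out/
```

prints

```
Payer (statutory insurance) perspective, EUR:
  inpatient case payments (actual)      196260.57
  inpatient savings from early discharge 18117.35
  outpatient total (drugs incl. fees)    57395.28
    of which clinic flat fees            1196.00
    of which drugs (net of fees)         56199.28
  net extra cost of OPAT                 39277.93

Provider (hospital) perspective, EUR:
  inpatient revenue (actual)             196260.57
  inpatient cost (actual)                252283.39
  contribution margin, actual            -56022.82
  contribution margin, simulated         -33426.57
  outpatient clinic margin               -1579.00
  net benefit of OPAT (revenue netted)   21017.25
  net benefit of OPAT (gross framing)    31847.57
  bed days freed                         159
```

Reading: early discharge would cost the payer 39,277.93 € extra (high
outpatient drug prices dominate), while the hospital's operating deficit on
these cases shrinks from −56,022.82 € to −33,426.57 € and 159 bed days are
freed — a 21,017.25 € net benefit even before any re-occupancy revenue.
`out/` additionally contains the six per-case tables (`table4.csv` …
`table9.csv`), `summary.json` and `summary.txt`.

Synthetic cohorts in the same schema:

```sh
opat-costsim simulate --n 100 --seed 42 --out cohort.csv
opat-costsim report --cohort cohort.csv --out out-synth/
```

## Layout

| module | contents |
| --- | --- |
| `tariff_model` | DRG catalogue, trimming-point and case-revenue arithmetic |
| `cohort_model` | case records, CSV I/O, inclusion screen, bundled fixtures |
| `discharge_simulation` | eligibility criteria and the counterfactual |
| `opat_costing` | clinic fees, drug bills, visit schedules |
| `perspectives_report` | ledgers, summary statistics, report output |
| `synthetic_cohort` | seeded generator for pools, cohorts and timelines |

See `docs/methods.md` for assumptions, parameter defaults and limitations.
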