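# stiecon

Whole-system cost analysis of clinic and online STI testing.

Online self-sampling services test more cheaply per kit than sexual-health
clinics, but they also shift activity between services and uncover new
demand, so their value can only be judged at the level of the whole local
sexual-health economy. `stiecon` implements that analysis as a reusable
pipeline for commissioners and health-economics researchers working with
GUMCAD-coded attendance data:

* **records** — typed attendance records (person, provider, day, up to 12
  GUMCAD codes) with a plain-CSV interchange format;
* **harmonisation** — exclusion filters, one-record-per-person-per-day
  collapse, and a six-week one-test-or-diagnosis-per-person deduplication;
* **metrics** — simple/complex and genital/triple-site visit classification,
  quarterly testing volumes and composite positivity (chlamydia, gonorrhoea,
  syphilis, HIV) by setting;
* **costing** — London integrated sexual-health tariff assignment and period
  cost summaries (annualised cost, monthly averages, cost per test, cost per
  diagnosis);
* **scenarios** — closed-form models of the blended system. With clinic cost
  `C`, online/clinic cost ratio `r`, online test share `f`, clinic
  positivity `p` and online/clinic positivity ratio `ρ`:

  cost per test = `C[(1−f) + f·r]`,
  cost per diagnosis = `C[(1−f) + f·r] / (p[(1−f) + f·ρ])` —
  and the break-even rule: growing the online share lowers the system's cost
  per diagnosis exactly when `ρ > r`. A return-rate model
  `c[s/R + (1−s)]` prices unreturned kits into the cost per completed test.
* **synthesis** — a seeded generator of realistic synthetic cohorts (the
  clinical datasets behind such evaluations are not shareable), so the whole
  pipeline is testable end to end.

## Worked example

Simulate a 20,000-person economy in which an online service launches in
April 2015 and takes ~44% of testing episodes (≈37% of completed tests at a
75% kit return rate), then run the full pipeline:

```sh
cat > demo.yaml <<EOF
seed: 7
n_persons: 20000
online_uptake_by_quarter: [0.439, 0.439, 0.439, 0.439, 0.439]
EOF
stiecon run-all --config demo.yaml --outdir demo_out
```

The harmonisation report (`demo_out/harmonisation_report.txt`):

```
n_input: 21933
n_excluded_no_codes: 1384
n_excluded_age: 104
n_excluded_prisoner: 42
n_collapsed_same_day: 0
n_removed_6week: 1739
n_output: 18664
online_return_rate: 0.7465
```

21,933 raw records (including dispatched-but-unreturned kits and
exclusion-triggering rows) reduce to 18,664 analysable attendances; the
count identity input − exclusions − collapsed − removed = output is asserted
at run time. The period comparison (`demo_out/period_costs.csv`, key
columns):

```
 period  n_clinic_visits  n_online_tests  combined_cost  annualised_cost  cost_per_test  cost_per_diagnosis
period1             7891               0         521108           521108             66                 623
period2             5501            3298         463360           370688             53                 611
```

In the baseline year every test happens in a clinic and the blended cost per
test is £66 (the tariff mix of £80.58 simple / £56.11 complex / £70.24
triple-site visits). After the online service launches, 3,298 of the
period-2 episodes complete online at £30 each, pulling the cost per test
down to £53 and the cost per diagnosis from £623 to £611 — online positivity
(7%) is lower than clinic positivity (10%), but its relative positivity
(0.7) is still above its relative cost (0.45), so the system gets cheaper
per diagnosis, exactly as the break-even rule predicts.

Scenario curves and the cross-area comparison need no simulated data:

```sh
stiecon scenario --model cost-per-diagnosis --vary positivity_ratio \
    --grid 0.1:1.0:0.1 --out curve.csv
stiecon areas --out areas.csv
```

`areas.csv` prices each area's chlamydia diagnoses at a common £66 clinic
cost and £30 online price over its observed positivities — e.g. a rural area
where clinic and online positivity are both 5.5% pays £1,200 per clinic
diagnosis but £545 online, while an urban reference area (7.5% clinic, 4.1%
online) pays £880 vs £732.

Every stage is also available as a library function
(`stiecon.synthesize_cohort`, `stiecon.harmonise`,
`stiecon.quarterly_summaries`, `stiecon.period_cost_summary`,
`stiecon.blended_cost_per_diagnosis`, …) and as individual subcommands
(`simulate`, `harmonise`, `summarise`, `cost`, `scenario`, `areas`).

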