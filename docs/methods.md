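# Methods

## Problem and data model

`stiecon` analyses the cost-effectiveness of STI testing across a whole
local sexual-health economy — specialist genito-urinary medicine (GUM)
clinics, community clinics and an online self-sampling service considered
jointly — rather than service by service. The unit of observation is one
attendance: one person at one provider on one calendar day, carrying up to
12 GUMCAD v2 sexual-health activity codes plus reproductive-health and
contraception codes. The composite outcome covers the four screened
infections (chlamydia, gonorrhoea, syphilis, HIV).

Code vocabularies are configurable with these defaults:

* **STI test**: `T1 T2 T3 T4 T7 T8 TT` — `T4` is genital-only testing, `TT`
  the triple-site (genital + rectal + oral) screen offered to men who have
  sex with men (MSM).
* **STI diagnosis**: `A1 A2 A3 A4 A5 B(R,O) C4(R,O) H1 H1a H1b`. Codes
  printed with site modifiers are matched by base code, so `B`, `B(R)` and
  `B(R,O)` are one diagnosis; the modifier semantics are not defined in the
  source coding sheet and are deliberately not interpreted.
* **Treatment-elsewhere** codes (treatment here for a diagnosis made at
  another service) suppress diagnosis counting for the matching base codes.
  No published list of these codes exists, so the default set is empty; the
  mechanism is exercised in tests with explicit codes.

## Harmonisation

1. **Exclusions.** Records with no codes in any list, age under 16 or 100
   and over, or a prisoner flag are dropped; each record is counted under
   the first matching reason (no-codes, then age, then prisoner).
2. **Same-day collapse.** One record per (person, provider, day); code lists
   merge as an order-preserving first-wins union, other fields come from the
   group's first record in input order.
3. **Six-week deduplication.** Clinic diagnoses are not reliably tied to a
   test episode, so each person contributes at most one test-or-diagnosis
   record per provider per six-week window. Operationally: sort a person's
   records by date; the selection pool is every record strictly within 42
   days of the earliest unresolved record (half-open window — a record
   exactly 42 days later is outside it); keep the pool record with the most
   diagnosis codes, ties broken by earliest date then stable input order;
   suppress everything else in the pool *and* any record strictly within 42
   days after the kept record. The suppression tail is what makes the rule
   idempotent and guarantees retained records are ≥ 42 days apart — with an
   earliest-anchored window alone, keeping a late, diagnosis-rich record can
   leave two retained records closer than the window. The greedy pass is
   verified against an exhaustive set-based restatement of the same rule on
   random small histories.

Deduplication scope is per provider by default (IDs are only unique within
a setting); a `person` scope is exposed for sensitivity analysis because the
source convention for a person testing at two clinics within six weeks is
unknown.

## Activity metrics

A visit is **simple** when its only coded services are tests or diagnoses,
**complex** when any code falls outside those vocabularies (treatment,
examination, reproductive or contraceptive care). Online visits are always
simple since the service provides nothing beyond the test. Positivity per
quarter and setting group is diagnoses over test-or-diagnosis episodes; the
denominator deliberately includes clinic diagnosis-only attendances (a
diagnosis made on contact tracing, symptoms or microscopy without a coded
simple test). The pooled row is the strict clinic + online sum. Note the
source publication's own pooled row differs slightly from its per-setting
sums (11,141 vs 11,150 in the first baseline quarter, unexplained there);
this package reports the strict sum.

## Costing

Tariffs (GBP, exact decimals throughout; rounding to whole pounds only at
presentation):

| tariff | default | applies to |
|---|---|---|
| primary simple | £80.58 | clinic genital test as the main activity |
| additional complex | £56.11 | clinic genital test alongside a costlier activity |
| MSM triple-site | £70.24 | clinic `TT` visits, flat across complexity |
| online price | £30 | each completed online test |
| clinic reference cost | £66 | scenario and cross-area models |

Clinic diagnosis-only visits are tariffed by their complexity class so the
visit denominator matches the costed population. Period outcomes use
unrounded intermediates: annualised cost = period cost × 12 / months (a
5-quarter period is scaled by 4/5 — the only reading that reproduces the
published annualisation); monthly tests/diagnoses/cost divide by the period
length; cost per test and per diagnosis are ratios of the unrounded monthly
figures. Recomputing the published period-1 cost per diagnosis from its own
printed inputs gives £659.4 → £659 where the source prints £660; presumed
rounding in the source, and not used as a check. Zero diagnoses leave cost
per diagnosis undefined (None), never infinite.

## Scenario models

With clinic unit cost `C`, online/clinic cost ratio `r`, online share of
tests `f`, clinic positivity `p`, online/clinic positivity ratio `rho`,
dispatch cost share `s` and kit return rate `R` (total testing volume held
constant):

* cost per test `C[(1-f) + f r]` — linear, decreasing in `f` iff `r < 1`;
* cost per diagnosis `C[(1-f) + f r] / (p[(1-f) + f rho])` — spend per test
  over diagnosis yield per test;
* break-even `rho* = r`: at `rho = r` the cost per diagnosis is `C/p` for
  *every* `f` (algebraic identity, grid-tested); above it, growing the
  online share lowers cost per diagnosis, below it raises it;
* online cost per completed test `c[s/R + (1-s)]`: `1/R` kits are dispatched
  per completed test and the dispatch share of the unit cost is sunk on
  every kit. At `s = 0.15` the markup over the nominal cost exceeds 10%
  exactly below `R = 0.6`.

These closed forms are the minimal models consistent with the published
assumptions and anchors; the source figures never print the formulas, so the
curves are regenerated from the models, not read off the figures. The
cross-area comparison divides a common clinic reference cost (£66) and
online price (£30) by each area's observed chlamydia positivity. The £30
area price and the £33 return-rate-curve price are both published
assumptions for different analyses; both are plain parameters here.

## Synthetic cohort generator

No attendance-level dataset is publicly deposited, so a generator emulates
the statistical structure the analysis assumes. Defaults are the observed
study conditions: study window 2014-01-01 to 2016-06-30 with the online
service starting 2015-04-01; clinic positivity 0.10; online positivity
0.07; kit return rate 0.75; 39% of baseline clinic test visits simple;
10.5% of clinic testers MSM (the published share of triple-site visit
categories); 10% repeat testers whose second visit falls 7–41 days after
the first at the same provider, guaranteeing six-week-window collisions;
exclusion-triggering records injected at small fixed fractions (1% no-code,
0.4% under-16, 0.1% 100+, 0.2% prisoner — placeholders, as the source
reports no exclusion tallies).

Design choices worth noting:

* **One random stream per cohort**, from a single explicit seed; same seed,
  byte-identical CSV.
* **Episode-level positivity.** A repeat tester's two visits share one
  positivity draw. Deduplication prefers the record with the most diagnosis
  codes, so independent per-visit draws would inflate recovered positivity
  (a max of two Bernoullis) and break the configured-vs-recovered identity
  the tests rely on; a retest within six weeks is also epidemiologically
  the same infection episode.
* **Uptake vs completed share.** The calibrated default targets a 37%
  online share of *completed* tests in the online era. Uptake applies to
  dispatched kits, of which only `R` return, so the per-quarter uptake is
  `u = sigma / (sigma + R(1 - sigma)) ≈ 0.439` for `sigma = 0.37`. The
  asymmetry of deduplication (a clinic repeat pair always collapses to one
  visit; an online pair only when both kits return) drifts the recovered
  share up by roughly half a point — well inside the Monte-Carlo tolerance
  used.
* Unreturned kits are emitted as online records with an empty code list and
  an `ordered_only` flag (an extension column in the CSV). The no-code
  exclusion removes them from all counting; only the return-rate accounting,
  which runs on raw records, sees them.

The generator does **not** emulate: demand growth over time (visit dates are
uniform over the window), seasonality, demographic or geographic structure
beyond uniform placeholders, per-infection breakdown, cross-provider
identity linkage, or any transmission dynamics — positivity is a configured
marginal, not an emergent rate. Passing parameter-recovery tests therefore
shows the pipeline measures what the generator encodes, not that the
generator reproduces real service dynamics.

## Verification strategy and problem sizes

The published intermediate quantities serve as exact oracles: quarterly
positivity cells, period cost outcomes and all eight cross-area cost cells
are recomputed from published counts, tariffs and positivities and must
match at the printed precision. Parameter recovery runs one 20,000-person
cohort (about 22,000 records, ~1 s to generate and harmonise) with
tolerances set at roughly three binomial standard errors of the relevant
denominators: ±0.01 clinic positivity, ±0.015 online positivity, ±0.02
online share, return rate and simple-visit share. The deduplication
property test checks 300 seeded random histories of up to 6 events in 120
days plus 500 hypothesis-generated ones (derandomised). The full suite runs
in a few seconds on one CPU.

## Known limitations

* Per-provider deduplication counts a person tested at two clinics within
  six weeks twice; the source convention is unknown (switchable).
* The empty default treatment-elsewhere vocabulary makes that exclusion a
  no-op until codes are supplied.
* Tariffs are London-specific; the cross-area model deliberately reuses
  them, which overstates cost per diagnosis where local clinic costs are
  lower.
* No statistical inference (no confidence intervals or tests) — the
  analysis is descriptive accounting plus deterministic closed forms, as in
  the source evaluation.
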