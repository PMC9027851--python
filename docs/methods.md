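# Methods

## Model

`cmm-bia` implements a deterministic, prevalence-based budget impact
analysis (BIA) of a pharmacist-led Comprehensive Medication Management
(CMM) service from a single payer's perspective. The comparator (usual
care) contributes no costs of its own; CMM is modelled as a pure add-on, so
the budget impact is simply

```
BI = C_total − S_total
```

where `C_total` are the direct programme costs (pharmacist labour,
training, therapy-modification costs) and `S_total` the induced savings
(avoided healthcare services plus avoided clinical events), both summed
over a short fixed horizon with no discounting and no currency conversion.
A negative `BI` means the programme is cost-saving (dominant).

### Population

The eligible population are patients with hypertension plus at least one
additional established cardiovascular disease (CVD) and/or type 2 diabetes
(DMT2), on medication, taking five or more medicines daily. Two groups are
carried: DMT2 + CVD and CVD-only, linked by a full-overlap assumption
(every DMT2 patient also has a CVD), so

```
n_dmt2_cvd = n_dmt2_on_med
n_cvd_only = n_combined_on_med − n_dmt2_on_med
```

Counts grow at a constant yearly prevalence growth rate `g` applied
multiplicatively to unrounded values (`n_{k+1} = n_k (1+g)`), then pass
through the polypharmacy fraction (default 0.85) and the per-year
enrollment fraction. **All downstream arithmetic consumes unrounded
counts**; half-up rounded counts exist only for display and headcounts.
This is deliberate: the published per-year cost cells replicate to the
euro only from unrounded enrolment, and two service categories whose
per-visit rates display as 0.000 still produce the published nonzero
savings — both facts identify the original computation as unrounded.

The on-medication counts themselves (240,398 and 765,687 in the built-in
scenario) are exogenous inputs. The prevalence chain that notionally
produces them (national population × prevalence × on-medication fraction)
does not reproduce them exactly and is therefore stored only as provenance
metadata, never recomputed.

### Costs

- Annual visits = unrounded enrolled × visits/patient-year. The constant
  2 visits/patient-year is not stated anywhere in the source material; it
  is forced by back-calculation (every published utilisation-savings cell
  equals rate × 2 × enrolled × price). It is an explicit scenario
  parameter, default 2.
- Pharmacist requirement: FTE = visits / 2,904 (11 visits/day × 264
  working days/year); headcount = half-up rounded FTE.
- Labour, `published_tables` mode: unrounded FTE × EUR 28,000 with no
  separate training term. This reproduces all three published per-year
  labour cells within a few euro, whereas the published per-year labour
  table's own totals do not sum to the published result-table cells. In
  `as_stated` mode the published per-year labour and training totals are
  taken verbatim as fixed inputs (generic fallback when absent:
  headcount × annual cost, new hires × EUR 200).
- Therapy modification: enrolled (unrounded) × EUR/patient-year. Default
  37.4733 in `published_tables` mode — the back-calculated constant
  (year-1 published cell ÷ unrounded year-1 enrolment, stable across all
  three years to four decimals) — and the published rounded 37.47 in
  `as_stated` mode.

### Savings: avoided services

Per-visit avoidance rates are transferred from a large US utilisation
study of the same CMM protocol: rate = avoided count ÷ 33,706 encounters,
kept at full precision. The clinic-outpatient count carries a 0.7
adjustment factor (pharmacists in Croatia cannot prescribe, so ~30% of
avoided GP visits still occur); the adjustment is a separate field so the
as-published source count remains visible. Savings per service-year =
rate × visits × local DRG unit price. Employee work days saved are priced
like any other service (EUR 47.19/day) because employment health benefits
are payer-funded in this system.

### Savings: avoided clinical events

Per-patient effective risk reduction:

```
Δrisk = (incidence per 1000 / 1000) × guideline RR × efficiency
```

`efficiency` (default 0.9) encodes that the pilot achieved 9 rather than
the guideline's 10 mmHg systolic reduction, assumed to scale the relative
risk reduction linearly (40% → 36%, 35% → 31.5%, 20% → 18%). Expected
avoided events = unrounded enrolled × Δrisk; savings price the *unrounded*
expectation at the event's unit cost (inpatient DRG + 21-day
rehabilitation proxy + pacemaker for heart failure; the fatal-MI cost
carries no follow-up). Avoided-event headcounts are half-up rounded per
cell and summed as integers.

### Published-tables overrides

The published parameter tables are internally inconsistent with the
published result tables in five places. `published_tables` mode carries
back-calculated effective values as explicit overrides; `as_stated` mode
uses the literal parameter-table values with no overrides. Both are
first-class parameterisations and are never merged:

| family | literal value | effective (published_tables) |
|---|---|---|
| Stroke / CVD risk reduction | 0.00243 | 0.0146 × 0.315 = 0.0045990 |
| Fatal MI / CVD risk reduction | 0.00157 | 0.018 × 0.18 = 0.00324 |
| Nonfatal MI unit cost | 2,982.20 | 864.79 |
| Angina unit cost | 2,303.51 | 864.79 |
| Revascularization unit cost | 2,237.83 | 864.79 |

Which side reflects the original authors' intent is undecidable from the
source; the package ships both and a cell-wise `compare` report.

Two further documented inconsistencies are *not* reproduced: the narrative
3-year savings figure EUR 7,787,765.60 (inconsistent with the two savings
tables, which sum to ≈7,757,094, and with the printed budget impact), and
the avoided-events grand total 2,742 (the printed per-cell counts sum to
2,741; this package reports the per-cell sum). The published "+5%" column
of the service-rate sensitivity table is arithmetically unrelated to a
1.05 scaling and is treated as a typesetting error; the sensitivity
*results* table is consistent with plain scaling and is what the scan
reproduces.

### Sensitivity analysis

Both savings-side rate families (service rates and risk reductions) are
scaled by one common multiplicative factor `f ∈ {1.05, 0.95, 0.80, 0.60}`
and the model is re-run. Savings ledgers are exactly linear in their
rates, so the scan obeys the closed form `BI(f) = C_total − f·S_total`
(asserted to 1e-9 relative in tests); "overestimation of the rates by x%"
corresponds to `f = 1 − x`. The break-even factor `C_total / S_total`
(≈1.012 in the built-in scenario) is reported alongside.

## Numerical conventions

- Currency is EUR throughout, held as doubles, never pre-rounded
  internally; comparisons happen at stated tolerances.
- Display rounding is half-up (`decimal.Decimal`), applied only in display
  columns and headcounts: integer EUR, 2-decimal per-patient costs,
  3-decimal per-visit rates, 5-decimal risks.
- Degenerate inputs: an empty cohort (zero enrolled headcount) yields
  per-patient metrics of 0 rather than a division error; empty service or
  event catalogues yield zero savings; the break-even factor is 0 when
  costs are 0 and undefined (error) when savings are 0 with positive
  costs.
- Unknown scenario keys are hard errors, so a typo in a parameter name can
  never silently fall back to a default.

## Synthetic scenarios

`random_scenario` draws every parameter independently from bounds that
bracket the built-in scenario's values (population 1e5–1e7 log-uniform,
on-medication fractions 0.01–0.5, growth −0.02–0.05, enrollment 0–0.2,
polypharmacy 0.5–1, visits/patient 1–4, therapy cost 5–100 EUR, avoided
counts 0–12,000 against 33,706 encounters, unit prices 5–5,000 EUR
log-uniform, incidence 0.5–50 per 1,000, guideline reductions 0.05–0.6,
efficiency 0.5–1). A single integer seed drives one stream with an
append-only draw order, so generation is byte-reproducible. The generator
provides bounds realism only: it makes no attempt at epidemiologically
plausible joint distributions, event recurrence, mortality feedback on
cohort size, or double counting across events (the model itself ignores
all of these too, by design). Passing property tests therefore establish
the model's accounting identities, linearity, monotonicity and
parameter-recoverability — not predictive validity on real populations.

Property sweeps use 200 generated scenarios (the full model runs in
milliseconds, so the suite stays in the seconds range); the recovery check
back-solves visits/patient-year and therapy cost/patient-year from the
output ledgers to 1e-9 relative, validating the same back-calculation
method that fixed the two reverse-engineered constants above.

## Known limitations

- No demographic structure, mortality attrition, event recurrence or
  double-counting correction; cohorts only shrink or grow via the scalar
  growth rate.
- No probabilistic sensitivity analysis and no per-parameter tornado
  scan; the deterministic common-factor scan mirrors the single-axis
  design of the original analysis.
- DRG unit costs and source-study rates enter as fixed constants; no
  uncertainty in them is modelled.
- The two-mode design quantifies, but cannot resolve, the documented
  internal inconsistencies of the source parameterisation.
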