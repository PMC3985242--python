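# Methods

## Model

`txcost` models the payer's cost of the first year after kidney
transplantation as a deterministic, additive, undiscounted build-up over a
closed incident cohort of `n` patients and a 365-day horizon:

```
total = hospitalization + maintenance + adverse events + miscellaneous
```

* **Hospitalization.** A global lump-sum tariff per recipient-donor
  operation pair, expressed as `multiplier × k_value` (the study inputs use
  650 × 60,000 IRR = 39,000,000 IRR), charged once per incident patient.
  Co-payments and out-of-pocket overflows beyond the tariff are outside the
  payer perspective and excluded.
* **Regimen lines** (maintenance and miscellaneous). Cohort cost is
  `units/day × unit price × eligible patients × duration (days)`. When a
  drug is dispensed as a dosage-form mixture whose proportions are not
  separable (cyclosporine in the study inputs: 25/50/100 mg capsules mixed
  per pharmacy records), the line instead carries a
  `cohort_daily_cost_override` — the recorded total cost per day for the
  whole eligible sub-cohort — and cohort cost is `override × duration`.
  A line may not have both drivers active.
* **Adverse events.** Each event has a marginal first-year occurrence
  probability `p` and an ordered bundle of treatment items: drug courses
  (`units/day × unit price × days`), procedures (`price × sessions`),
  hospitalization days (`price/day × days`) and fixed tariffs. Events are
  treated as independent Bernoulli occurrences per patient; expected cost
  per patient is `p × bundle cost` and the cohort total is
  `p × bundle cost × n` computed from the unrounded expectation. One event
  in the study inputs ("other infections") has `p = 1` and acts as a
  certain per-patient cost. Graft failure's re-transplantation tariff is
  charged within year 1 with no recursive downstream costs — this matches
  the additive expected-cost arithmetic of the source tables.

## Money and rounding

Money is an exact integer count of IRR; probabilities, units/day and
currency rates are exact `fractions.Fraction` values. No binary floating
point enters any total, so results are bit-reproducible.

The rounding policy, applied only at display edges, is **half away from
zero**:

* per-event expected cost per patient is rounded for display, and the
  per-patient *column sum* adds the rounded values (the study table's
  19,645,885 includes hypertension's 36,683 = round(36,682.5));
* per-event *cohort* totals multiply the unrounded expectation by `n`
  (hypertension: 36,682.5 × 2,200 = 80,701,500 — rounding first would give
  80,702,600);
* USD values are `round(irr / rate)` per displayed IRR figure; per-patient
  USD converts the already-rounded per-patient IRR;
* the per-patient IRR total is `round(total / n)` (170,718,326,900 / 2,200 =
  77,599,239.5 → 77,599,240).

This combination reproduces every IRR and USD cell of the bundled input's
published tables exactly; the dual per-patient/cohort paths are both
exposed (`AEExpected.expected_display` vs `.cohort_total`).

## Monte Carlo simulation

`simulate_cohort` draws, for each of `R` replicates, an event-by-patient
Bernoulli occurrence matrix (`uniform(E, n) < p`, one
`numpy.random.default_rng(seed)` stream), sums the corresponding bundle
costs, and stores each replicate's mean cost per patient as an exact
rational. The analytic expectation `Σ p(e)·c(e)` rides along for
comparison. `convergence_check` passes when
`|grand mean − analytic| ≤ tol × sd(replicate means)/√R`, with `tol = 4`
standard errors by default; a degenerate simulation (zero spread) passes
only on exact agreement. Replicates default to 500 — inside the 100–1,000
range the validation design calls for — and the seed is mandatory on the
CLI.

Independence across events and across patients is an assumption, not an
estimate: only marginal probabilities are available, and the expectation
arithmetic being validated is agnostic to the dependence structure. The
simulator's noise is pure Bernoulli sampling variation; unit prices are
fixed (a multiplicative price-jitter knob exists in the generator, default
off, for stress-testing rounding only).

## Comparator

The hemodialysis arm is `session tariff × sessions/year × n` plus an
annual per-patient adjunct bundle (erythropoietin, calcitriol) × `n`, with
no adverse-event layer. `sessions_per_year` defaults to 156 (3/week × 52),
consistent with both standard hemodialysis practice and the published
annual dialysis total; the adjunct bundle is a single opaque annual amount
per patient (21,230,400 IRR in the bundled inputs, the published cohort
figure divided by 2,200) because no dose/price breakdown is available.
`compare_strategies` emits signed incremental totals (B − A), component
deltas and the per-patient cost ratio as an exact rational; scenario
substitution (e.g. swapping an immunosuppressant line) is expressed by
building strategy B from A's parts and diffing — no special machinery.

## Synthetic data generator

`generate_strategy` draws structurally valid strategies: cohort sizes,
prices and durations uniform on integer ranges, probabilities uniform on a
1/1000 rational grid inside the requested sub-interval (keeping all
expectations exact), one in five regimen lines an override line, and every
event at least one item. Its purpose is structural coverage of the engine —
additivity, scaling, rounding, serialization — not clinical realism:
passing property tests says the arithmetic is right for any input of this
shape, not that generated prices resemble a real formulary. Defaults
(cohort 50–5,000, 1–5 events of 1–4 items, prices 50–2,000,000 IRR,
durations 1–365 days) bracket the magnitudes of the bundled inputs.

## Numerical and design choices

* Reference patient weight 70 kg: reproduces the tacrolimus line
  (0.2 mg/kg/day ⇒ 14 mg ⇒ 28 × 0.5 mg tablets at 1,000 IRR = 28,000
  IRR/day) and ganciclovir's 2 vials/day (5 mg/kg q12h ⇒ 350 mg/dose ⇒ one
  500 mg vial per dose); used only for dose-consistency reasoning, never
  for costing.
* Tacrolimus eligibility 220 of 2,200 (patients on a second or later
  graft, ~10%); cyclosporine covers the remaining 90%. Sirolimus is
  excluded from the bundled inputs: it had no insurance coverage in the
  study year, and the model is payer-perspective.
* A cohort of zero patients is representable (cost 0) but a per-patient
  cost over zero patients is an explicit error rather than a NaN.
* Rounded per-event cohort totals make "doubling the cohort doubles the
  total" exact only up to one rounding unit per event; tests assert the
  exact statement on the unrounded expectations and the ±1-per-event bound
  on the rounded ones.
* Validation raises `ValidationError`/`SchemaError` with the config path of
  the offending field; unknown fields are rejected rather than ignored.

## Problem sizes in the test suite

The acceptance-level tests run the full study configuration: 500 replicates
of 2,200 patients for the Monte Carlo check, 1,000 randomized strategies
against an independent exact-rational brute-force oracle, and
noise-scaling checks at cohort sizes 100/400/1,600 with 500 replicates
each. The whole suite completes in a few seconds on one CPU.

## Limitations

One-year horizon, no discounting, no multi-year graft-survival dynamics,
no QALY/DALY outcomes, no estimation of event probabilities from data, no
correlated-event structure, no peritoneal-dialysis arm, and no
patient-level covariates. Costs reflect a single tariff year and a single
currency rate; no inflation adjustment is attempted.
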