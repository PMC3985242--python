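# Strategy config schema (version 1)

A strategy is one YAML or JSON document. All money values are integer IRR;
probabilities and units/day may be integers, decimal strings/numbers
(`0.21`) or fraction strings (`21/100`) and are parsed exactly. Unknown
fields are rejected with the path of the offending field. The bundled
example `src/txcost/fixtures/iran_rtt_2011.yaml` exercises every feature.

```yaml
schema_version: 1          # optional, must be 1 when present
name: my-strategy          # required
currency_rate_irr_per_usd: 12260   # optional; IRR per USD

cohort:                    # required
  n_patients: 2200         # required, >= 0
  horizon_days: 365        # optional, default 365
  patient_weight_kg: 70    # optional, default 70; dose sanity checks only

hospitalization:           # optional lump-sum tariff per operation pair
  k_value: 60000           # IRR per tariff unit K
  multiplier: 650          # number of K units, >= 1

maintenance_lines:         # optional list of regimen lines
  - drug_name: Example     # required
    dosage_form: "tab: 5 mg"        # optional, informational
    units_per_day: 1                # dispensed units per patient per day
    unit_price: 130                 # IRR per unit
    n_eligible: 2200                # patients on this line
    duration_days: 365              # default 365
    # cohort_daily_cost_override: 5167800
    #   total IRR/day for the whole eligible sub-cohort; when set, the
    #   per-patient fields must be cost-inert (their product zero)

adverse_events:            # optional list
  - name: CMV              # required
    probability: 0.21      # required, in [0, 1]
    items:                 # treatment bundle, billed per affected patient
      - kind: drug_course  # drug_course | procedure | hospitalization | fixed_tariff
        label: Ganciclovir
        units_per_day: 2   # drug_course only, > 0
        unit_price: 250000 # per unit / session / day / the fixed amount
        duration: 7        # days (drug_course, hospitalization),
                           # sessions (procedure), ignored (fixed_tariff)

misc_lines: []             # optional, same shape as maintenance_lines

dialysis:                  # optional comparator block (read_dialysis_arm)
  session_tariff: 743200
  sessions_per_year: 156           # default 156 (3/week x 52)
  adjunct_annual_per_patient: 21230400
  name: hemodialysis
```

## CSV import

`strategy_from_csv_dir(directory)` assembles a strategy from flat tables:

* `strategy.csv` — `key,value` rows: `name`, `n_patients`, `horizon_days`,
  `k_value`, `multiplier`;
* `maintenance.csv`, `misc.csv` — regimen-line columns as above;
* `adverse_events.csv` — `name,probability`;
* `ae_items.csv` — `event` plus the treatment-item columns.

Values are read as text and parsed exactly; empty cells mean "use the
default".
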