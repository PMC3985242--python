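# First-year renal-transplantation cost inputs, Iran, study year 2011-2012,
# payer (insurance-organization) perspective.  Canonical config schema v1;
# see docs/config_schema.md.  All money values are integer IRR.
schema_version: 1
name: iran-rtt-2011
currency_rate_irr_per_usd: 12260

cohort:
  n_patients: 2200          # incident transplant operations in the study year
  horizon_days: 365
  patient_weight_kg: 70     # reference weight for dose sanity checks only

# Global lump-sum tariff per recipient-donor operation pair: 650 K units.
hospitalization:
  k_value: 60000
  multiplier: 650

maintenance_lines:
  # Cyclosporine is dispensed as a mixture of 25/50/100 mg capsules whose
  # proportions are known only to the dispensing pharmacies, so the line is
  # driven by the recorded cohort-wide cost per day; the per-patient fields
  # are informational.
  - drug_name: Cyclosporine (generic)
    dosage_form: "cap: 25, 50, 100 mg"
    units_per_day: 0
    unit_price: 0
    n_eligible: 1980
    duration_days: 365
    cohort_daily_cost_override: 5167800
  - drug_name: Mycophenolate mofetil
    dosage_form: "cap: 500 mg"
    units_per_day: 4          # 2 g/day
    unit_price: 11000
    n_eligible: 2200
    duration_days: 365
  - drug_name: Prednisolone
    dosage_form: "tab: 5 mg"
    units_per_day: 1
    unit_price: 130
    n_eligible: 2200
    duration_days: 365
  - drug_name: Tacrolimus
    dosage_form: "tab: 0.5 mg"
    units_per_day: 28         # 0.2 mg/kg/day at 70 kg
    unit_price: 1000
    n_eligible: 220           # second-or-later transplants, ~10% of cohort
    duration_days: 365

adverse_events:
  - name: CMV
    probability: 0.21
    items:
      - {kind: drug_course, label: Ganciclovir, units_per_day: 2, unit_price: 250000, duration: 7}
      - {kind: hospitalization, label: Hospitalization, unit_price: 1600000, duration: 7}
  - name: Other infections
    probability: 1
    items:
      - {kind: drug_course, label: Co-trimoxazole, units_per_day: 2, unit_price: 210, duration: 180}
      - {kind: drug_course, label: Cefazoline, units_per_day: 3, unit_price: 6000, duration: 2}
      - {kind: drug_course, label: Nystatin, units_per_day: 4, unit_price: 450, duration: 180}
      - {kind: drug_course, label: Fluconazole, units_per_day: 1, unit_price: 1200, duration: 180}
  - name: Delayed graft function
    probability: 0.17
    items:
      - {kind: drug_course, label: ATG, units_per_day: 4, unit_price: 550000, duration: 10}
      - {kind: drug_course, label: Ganciclovir (prophylaxis), units_per_day: 1, unit_price: 250000, duration: 10}
      - {kind: procedure, label: Dialysis, unit_price: 743200, duration: 3}
  - name: Acute rejection
    probability: 0.18
    items:
      - {kind: drug_course, label: Methylprednisolone, units_per_day: 1, unit_price: 200000, duration: 7}
      - {kind: drug_course, label: ATG, units_per_day: 4, unit_price: 550000, duration: 7}
      - {kind: drug_course, label: Ganciclovir (prophylaxis), units_per_day: 1, unit_price: 250000, duration: 7}
      - {kind: hospitalization, label: Hospitalization, unit_price: 1600000, duration: 7}
  - name: Hyperlipidemia
    probability: 0.14
    items:
      - {kind: drug_course, label: Atorvastatin, units_per_day: 1, unit_price: 1100, duration: 365}
  - name: Hypertension
    probability: 0.67
    items:
      - {kind: drug_course, label: Amlodipine, units_per_day: 1, unit_price: 150, duration: 365}
  - name: Graft failure
    probability: 0.105
    items:
      - {kind: procedure, label: Dialysis, unit_price: 743200, duration: 10}
      - {kind: fixed_tariff, label: Re-transplantation (650 K), unit_price: 39000000}
  - name: Thrombocytopenia
    probability: 0.08
    items:
      - {kind: procedure, label: Plasmapheresis, unit_price: 1300000, duration: 10}

misc_lines:
  - {drug_name: Calcitriol, dosage_form: "cap: 0.25 mcg", units_per_day: 1, unit_price: 2300, n_eligible: 2200, duration_days: 365}
  - {drug_name: Ferrous sulphate, dosage_form: "tab: 50 mg", units_per_day: 1, unit_price: 55, n_eligible: 2200, duration_days: 365}
  - {drug_name: A.S.A, dosage_form: "tab: 80 mg", units_per_day: 1, unit_price: 83, n_eligible: 2200, duration_days: 365}
  - {drug_name: Ranitidine, dosage_form: "tab: 150 mg", units_per_day: 1, unit_price: 55, n_eligible: 2200, duration_days: 365}
  - {drug_name: Calcium carbonate, dosage_form: "tab: 500 mg", units_per_day: 1, unit_price: 155, n_eligible: 2200, duration_days: 365}

# Comparator: every cohort patient on hospital-based hemodialysis instead,
# three sessions a week, plus an annual adjunct bundle (erythropoietin,
# calcitriol) per patient.  No adverse-event layer.
dialysis:
  session_tariff: 743200
  sessions_per_year: 156
  adjunct_annual_per_patient: 21230400
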