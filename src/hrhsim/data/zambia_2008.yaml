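# Zambia public-sector health workforce, 2008 baseline.
#
# Stocks come from Ministry of Health payroll data (September 2008); training
# parameters from the 2008 national assessment of all 39 medical training
# institutions; staffing targets are the MOH minimum-need levels, held fixed
# across the projection horizon. Rates are stored exactly as published
# (three significant digits); the voluntary/involuntary split of attrition is
# given directly per class and must sum to the published total.
baseline_year: 2008
horizon_year: 2018
capping_enabled: true
attrition_report_shares:
  retirement: 0.10
  involuntary_other: 0.58
  voluntary: 0.32
stock_classes:
- id: doctors
  reporting_cadre: doctors
  baseline_stock: 806
  attrition:
    voluntary: 0.0314
    involuntary: 0.0666
  immigration: 20
- id: clinical_officers
  reporting_cadre: clinical_officers
  baseline_stock: 1236
  attrition:
    voluntary: 0.0143
    involuntary: 0.0305
- id: registered_nurses
  reporting_cadre: nurses
  baseline_stock: 1453
  attrition:
    voluntary: 0.0170
    involuntary: 0.0360
- id: enrolled_nurses
  reporting_cadre: nurses
  baseline_stock: 5134
  attrition:
    voluntary: 0.0143
    involuntary: 0.0305
- id: registered_midwives
  reporting_cadre: midwives
  baseline_stock: 339
  attrition:
    voluntary: 0.0143
    involuntary: 0.0305
- id: enrolled_midwives
  reporting_cadre: midwives
  baseline_stock: 1711
  attrition:
    voluntary: 0.0143
    involuntary: 0.0305
- id: direct_entry_midwives
  reporting_cadre: midwives
  baseline_stock: 0
  attrition:
    voluntary: 0.0143
    involuntary: 0.0305
programs:
- id: medicine
  output_class: doctors
  duration_years: 7
  annual_enrolment: 74
  graduation_rate: 0.900
  entry_rate: 0.853
- id: clinical_officer_training
  output_class: clinical_officers
  duration_years: 3
  annual_enrolment: 155
  graduation_rate: 0.900
  entry_rate: 0.914
- id: registered_nursing
  output_class: registered_nurses
  duration_years: 3
  annual_enrolment: 660
  graduation_rate: 0.967
  entry_rate: 0.755
  feeder:
    source_class: enrolled_nurses
    fraction: 0.1489
- id: enrolled_nursing
  output_class: enrolled_nurses
  duration_years: 2
  annual_enrolment: 423
  graduation_rate: 0.943
  entry_rate: 0.814
- id: registered_midwifery
  output_class: registered_midwives
  duration_years: 1
  annual_enrolment: 136
  graduation_rate: 0.971
  entry_rate: 0.814
  feeder:
    source_class: registered_nurses
    fraction: 1.0
- id: enrolled_midwifery
  output_class: enrolled_midwives
  duration_years: 1
  annual_enrolment: 173
  graduation_rate: 0.907
  entry_rate: 0.814
  feeder:
    source_class: enrolled_nurses
    fraction: 1.0
- id: direct_entry_midwifery
  output_class: direct_entry_midwives
  duration_years: 2
  annual_enrolment: 174
  graduation_rate: 0.900
  entry_rate: 0.814
reporting_cadres:
- id: doctors
  members: [doctors]
  target_stock: 1778
- id: clinical_officers
  members: [clinical_officers]
  target_stock: 3737
- id: nurses
  members: [registered_nurses, enrolled_nurses]
  target_stock: 14053
- id: midwives
  members: [registered_midwives, enrolled_midwives, direct_entry_midwives]
  target_stock: 4751
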