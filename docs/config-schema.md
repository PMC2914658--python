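# Configuration file schema

Model configurations are YAML mappings. Unknown keys are rejected anywhere
in the file. The packaged example is
`src/hrhsim/data/zambia_2008.yaml`.

```yaml
baseline_year: 2008          # int, required
horizon_year: 2018           # int, required; > baseline_year
capping_enabled: true        # bool, default true
attrition_report_shares:     # optional; defaults shown; must sum to 1
  retirement: 0.10
  involuntary_other: 0.58
  voluntary: 0.32

stock_classes:               # one entry per workforce compartment
- id: doctors                # unique across classes
  reporting_cadre: doctors   # must match a reporting_cadres id
  baseline_stock: 806        # persons at the baseline year, >= 0
  attrition:                 # annual fractions of pre-hire stock
    voluntary: 0.0314        # either give both components ...
    involuntary: 0.0666
    # total: 0.0980          # ... or only total (split by the report
                             # shares); if both forms are present they
                             # must agree to 1e-6
  immigration: 20            # persons/yr from abroad, optional, >= 0

programs:                    # one entry per training program
- id: medicine               # unique across programs
  output_class: doctors      # stock class its graduates join
  duration_years: 7          # integer >= 1
  annual_enrolment: 74       # students/yr, >= 0 (fractional allowed)
  graduation_rate: 0.900     # in [0, 1]
  entry_rate: 0.853          # public-sector entry rate, in [0, 1]
  feeder:                    # optional: enrolment drawn from the workforce
    source_class: enrolled_nurses
    fraction: 0.1489         # share of each cohort, in [0, 1]

reporting_cadres:            # targets/caps apply to summed member stocks
- id: doctors
  members: [doctors]         # member lists must partition the classes and
                             # agree with each class's reporting_cadre
  target_stock: 1778         # persons, > 0
```

Validation additionally requires: all cross-references resolve; feeder
links form a DAG over stock classes; `horizon_year > baseline_year`.

## Output files

All CSVs are RFC-4180 (CRLF, header row, UTF-8).

* `trajectory.csv` — columns `year, stock_class, stock, hires, immigration,
  attrition_retire, attrition_involuntary, attrition_voluntary,
  school_outflow`; one row per simulated year × stock class; flows are the
  amounts realized during the transition *into* that year (zero in the
  baseline year); full floating precision.
* `table2.csv` — flow-ledger report: rows are flow categories
  (a–h plus totals), columns are cadres plus `combined`, values rounded
  half-up to whole persons.
* `table3.csv` — scenario suite: columns `scenario, cadre, stock_<horizon>,
  pct_of_target`.
* `summary.csv` — columns `cadre, year, stock, target, pct, gap`.
* `grid_<cadre>.csv` — integer multiplier matrix; attrition rows,
  graduation×entry columns.
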