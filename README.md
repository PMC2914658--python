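# hrhsim

Stock-and-flow projection of a public-sector health workforce, built for
human-resources-for-health (HRH) planning: given a country's baseline
head-counts, training-school throughput and attrition rates, how many
doctors, clinical officers, nurses and midwives will the public sector
employ in ten years — and what combination of policy levers (training
enrolment, graduation rates, public-sector entry rates, retention) reaches
the staffing targets by the deadline?

The package ships the published Zambia 2008 parameter set (Ministry of
Health payroll and a national assessment of all 39 medical training
institutions) as a built-in fixture, and reproduces that analysis end to
end; any other workforce can be described in a small YAML file.

## The model

Each workforce compartment ("stock class") `c` evolves annually:

    N_c(Y+1) = (N_c(Y) − S_c(Y+1)) · (1 − a_c(Y)) + H_c(Y+1) + m_c(Y+1)

* `a_c` — annual attrition rate (voluntary + involuntary), applied to the
  pre-hire stock;
* `m_c` — hires from abroad (persons/yr);
* `S_c` — back-to-school outflow: feeder-linked training programs draw a
  fraction `f` of each entering cohort out of the serving workforce (e.g.
  enrolled nurses leaving to train as midwives), so `S` scales with the
  destination programs' enrolment;
* `H_c` — hires from training. A cohort of `E` students enrolling in year
  `e` in a program of duration `d` is hired in year `e + d + 1`
  (graduation plus one hiring year):

      H(Y) = E(Y − d − 1) · g(Y − 1) · p(Y − 1)

  with graduation rate `g` and public-sector entry rate `p`. The pipeline
  is pre-filled at baseline enrolment, so hires flow at the steady-state
  rate from the first projected year.

Policy changes ramp in linearly from the baseline year to an effect year
(default: baseline + 2) and hold thereafter. Staffing targets act as
anticipatory caps: if a cadre would exceed its target, enrolment in the
cohorts feeding the overshooting hire years is reduced (propagating to
feeder outflows) so the stock meets but never exceeds the target.

On top of the simulator sit three solvers: the *equilibrium enrolment*
that sustains a cadre exactly at its target (`E·g·p = a·T + S − m`), the
*minimum enrolment multiplier* that reaches the target by the horizon
(bisection on the monotone horizon stock), and a multiplier *grid* over
attrition × (graduation·entry) values.

## Worked example

```
$ hrh project --out out/
            cadre  year  stock  target  pct     gap
          doctors  2018    792  1778.0 44.5   986.0
clinical_officers  2018   1828  3737.0 48.9  1909.0
           nurses  2018   7425 14053.0 52.8  6628.0
         midwives  2018   4273  4751.0 89.9   478.0
         combined  2018  14317 24319.0 58.9 10002.0
```

Under unchanged conditions the Zambian workforce grows from 10 679 (44% of
need) in 2008 to ~14.3 k (59%) in 2018 — doctors actually *shrink* (806 →
792) because attrition and the 8-year medical pipeline outpace current
enrolment. `out/table2.csv` decomposes the change into the full flow
ledger (enrolled / failed / not hired / from abroad / retirement /
involuntary / voluntary / back-to-school).

```
$ hrh solve multiplier --cadre doctors
doctors: x13 (continuous 12.965); required enrolment 960/yr; horizon stock 1781

$ hrh solve equilibrium
doctors: 201 students/yr (continuous 200.9; per program medicine=200.9)
clinical_officers: 204 students/yr (continuous 203.5; per program clinical_officer_training=203.5)
...
```

Reaching the doctor target of 1778 by 2018 takes a thirteen-fold enrolment
increase (74 → 960 students/yr) at current rates; once the target is
reached, only 201/yr are needed to hold it. The same API is available in
Python:

```python
from hrhsim import zambia_fixture, run_projection, single_variable_suite

config = zambia_fixture()
trajectory = run_projection(config)
trajectory.stock("doctors", 2018)        # 791.7
single_variable_suite(config)            # the what-if comparison table
```

Scenarios are parameter overrides with a linear ramp-in, e.g.
`hrh scenario --set doctors.attrition.voluntary=0@2010` or
`hrh suite` for the standard single-intervention table (perfect
graduation, perfect entry, zero voluntary attrition, 2× and 3× enrolment).

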