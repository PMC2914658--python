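# Methods

## Model

The simulator is a deterministic annual cohort stock-and-flow model of a
public-sector health workforce. State consists of the head-count of each
*stock class* (a workforce compartment such as enrolled nurses, with its own
attrition rates) and the cohorts currently in training. The transition from
year `Y` to `Y+1` is, per class,

    N(Y+1) = (N(Y) − S(Y+1)) · (1 − a(Y)) + H(Y+1) + m(Y+1)

with back-to-school outflow `S`, attrition rate `a`, training hires `H` and
immigration `m`. Stocks are continuous reals throughout; rounding to whole
persons (half-up) happens only when reports are formatted.

### Timing conventions

These conventions are deliberate and load-bearing; changing any of them
breaks the reproduction of the published Zambia results.

* **Pipeline lag `d + 1`.** A cohort enrolling in year `e` in a program of
  duration `d` trains during years `e … e+d−1`, graduates, and is hired one
  year later: `H(Y) = E(Y−d−1) · g(Y−1) · p(Y−1)`. The full pipeline for a
  7-year medical degree is therefore 8 years.
* **Rates in force.** The attrition rate during year `Y` governs the
  transition into `Y+1`; graduation and entry rates applied to a hire in
  year `Y` are those of year `Y−1`.
* **Order of outflows.** Back-to-school leavers depart at the start of the
  year (before attrition is applied); the leavers joining a cohort that
  enrols in year `e` are removed in the transition into year `e`.
* **Immigration** enters with hires, after attrition, and is not thinned in
  its first year.
* **Pipeline initialization.** Cohorts for enrolment years
  `baseline − d … baseline` are synthetically pre-filled at the baseline
  enrolment, so every program — including one whose output class starts at
  zero stock, like direct-entry midwives — delivers steady-state hires from
  the first projected year. This is the assumption that the training system
  was already running at its baseline throughput before the projection
  window opens.
* **Negative stocks** cannot arise under the packaged parameters; if a
  pathological configuration drains a class (e.g. a feeder outflow larger
  than the source stock), the stock is clamped at zero and a warning is
  logged. The per-year conservation identity is exact wherever the clamp
  does not fire.

### Scenario ramps

A policy change is a linear ramp from the baseline-year value to the new
value at an *effect year* (default baseline + 2, i.e. 2010 for the Zambia
set), held constant thereafter; with the default years the intermediate
year takes the midpoint. Enrolment multipliers apply proportionally to
every program of a cadre. Combined graduation×entry sweeps are implemented
through the entry rate with graduation untouched; under the timing above,
horizon stocks depend on the two rates only through their product, so the
choice is immaterial (asserted by a property test, which also tolerates
entry values above 1 used internally to encode a product).

### Target capping

When enabled, a reporting cadre's stock never exceeds its staffing target:
the engine looks ahead `d + 1` years and shrinks the cohorts feeding an
overshooting hire year, allocating the cut across the cadre's programs in
proportion to their planned enrolments (equivalently: uniformly in relative
terms), so that in the first capped year the stock equals the target
exactly and thereafter hires exactly replace exits. Because a smaller
cohort also means fewer feeder-class workers leaving for school in the
cohort's *enrolment* year — which precedes the capped hire year — the
trajectory is resolved by fixed-point iteration on realized enrolments
(tolerance 1e-9, limit 100 passes; feeder links are validated to form a
DAG, and the packaged set converges in 2–3 passes).

The capped simulation internally runs `max(duration) + 1` years past the
reporting horizon and is then truncated. Without this, cohorts whose hire
year falls just beyond the horizon would escape the cap and snap back to
scenario-level enrolment, inflating back-to-school outflows in the last
reported years; a planner who has cut training slots to hold a cadre at its
target does not re-expand them merely because the report ends. Base-case
results inside the window are unaffected.

## Parameters

The packaged Zambia 2008 set (see `docs/config-schema.md` for the file
format): 7 stock classes, 7 programs, 4 reporting cadres, horizon 2008 →
2018. Rates are stored exactly as published (three significant digits); no
hidden precision is invented. Attrition may be specified as a
voluntary/involuntary split (the published per-class values) or as a total
split by the reporting shares; when both are given they must agree to 1e-6.
The reporting decomposition of attrition uses shares (retirement 0.10,
involuntary-other 0.58, voluntary 0.32 of total), with retirement carved
out of the involuntary component — so a scenario that zeroes voluntary
attrition still reports retirement correctly.

Solver tunables: bisection on the continuous enrolment multiplier over
[1, 1000] to 1e-6 (the horizon stock is monotone in the multiplier);
equilibrium enrolments solved as a fixed point across cadres to 1e-12
(feeder links couple a cadre's requirement to destination cadres'
equilibrium enrolments). Within a multi-class cadre the target head-count
is allocated across classes in proportion to baseline stocks when
computing equilibrium attrition, since classes may carry different rates.
Reported enrolments are rounded *up* to whole students — a fractional
student cannot be enrolled, and rounding down would miss the target.

## Synthetic configurations

`random_config(seed, n_classes)` generates valid random models for property
testing: attrition totals in [0, 0.15], graduation/entry rates in
[0.5, 1.0], durations 1–7 years, enrolments in [0, 1000], optional one-level
acyclic feeders, horizons 5–14 years. It emulates the *structure* of a real
workforce model, not its magnitudes: stocks and targets are arbitrary, all
parameters are constant in time, and feeder chains are at most one level
deep. Tests passing on these configurations demonstrate the engine's
arithmetic (conservation, closed-form agreement, monotonicity), not the
realism of any particular country scenario; realism rests on the published
parameter set.

Feeder-free random configurations admit an exact closed form (constant
rates, steady pipeline): `N_k = (1−a)^k N_0 + (H+m)(1−(1−a)^k)/a`; the
simulator must agree to a relative 1e-9, which is the engine's primary
independent oracle.

## Known limitations

* Deterministic only: no stochastic attrition, no uncertainty intervals.
* Annual resolution; no within-year dynamics, no age structure.
* Targets are fixed over the horizon (no population growth adjustment).
* Training slots are assumed always fillable with qualified students, and
  the public sector is assumed able to absorb all graduates.
* The published nurse figures are not exactly reproducible from the
  published parameter table: the printed registered-nurse public-sector
  entry rate (75.5%) is inconsistent with the source's own inflow
  accounting, which implies roughly 80%. With the printed rates the 2018
  nurse stock computes ~1.1% low and the ten-year nurse inflow ~3.5% low;
  this package keeps the printed parameters rather than back-fitting an
  effective rate, and its tests check those figures as relative tolerances.
  All doctor, clinical-officer and midwife results, and all combined
  scenario totals, reproduce the published values to ±1 person or better
  than 2%.
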