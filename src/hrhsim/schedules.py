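"""Time-varying parameter schedules with linear ramp-in.

Policy changes are modelled as a linear ramp from the baseline-year value to
a new value reached at an *effect year* (two years after baseline by
default) and held constant thereafter.  With the default fixture years this
means the intermediate year takes the midpoint of the old and new values --
e.g. a doubling of enrolment announced in 2008 and effective 2010 runs at
1.5x in 2009.

An :class:`Override` names one parameter by a dotted path and gives its new
value; :func:`compile_schedules` resolves a list of overrides against a
model configuration into one :class:`Schedule` per parameter, which the
projection engine evaluates year by year.

Recognised override paths (first segment is a stock-class or program id):

==============================================  =================================
path                                            meaning
==============================================  =================================
``<class>.attrition.total``                     rescale voluntary + involuntary
                                                proportionally to a new total
``<class>.attrition.voluntary``                 new voluntary rate, involuntary
                                                unchanged (total moves with it)
``<class>.immigration``                         new annual inflow from abroad
``<program>.enrolment``                         new annual enrolment (students)
``<program>.enrolment_multiplier``              enrolment as a multiple of the
                                                configured baseline
``<program>.graduation_rate``                   new graduation rate
``<program>.entry_rate``                        new public-sector entry rate
==============================================  =================================
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .params import ConfigError, ModelConfig

__all__ = ["Schedule", "build_schedule", "constant_schedule", "Override",
           "ScheduleSet", "compile_schedules"]


@dataclass(frozen=True)
class Schedule:
    """Piecewise-linear annual value: flat, ramp, flat.

    ``value(y)`` equals ``baseline_value`` for ``y <= ramp_start``,
    ``target_value`` for ``y >= effect_year`` and interpolates linearly in
    between.  When ``effect_year == ramp_start`` the change is a step: the
    target applies from the start year onward.
    """

    baseline_value: float
    target_value: float
    ramp_start: int
    effect_year: int

    def value(self, year: int) -> float:
        if year >= self.effect_year:
            return self.target_value
        if year <= self.ramp_start:
            return self.baseline_value
        frac = (year - self.ramp_start) / (self.effect_year - self.ramp_start)
        return self.baseline_value + (self.target_value - self.baseline_value) * frac

    @property
    def is_constant(self) -> bool:
        return self.baseline_value == self.target_value


def build_schedule(v0: float, v1: float, start: int, effect: int) -> Schedule:
    """A schedule ramping from ``v0`` at ``start`` to ``v1`` at ``effect``."""
    if effect < start:
        raise ValueError(f"effect year {effect} before ramp start {start}")
    return Schedule(float(v0), float(v1), int(start), int(effect))


def constant_schedule(v: float) -> Schedule:
    return Schedule(float(v), float(v), 0, 0)


@dataclass(frozen=True)
class Override:
    """One scenario override: parameter path, new value, effect year.

    ``effect_year=None`` means the model default (baseline year + 2).
    """

    path: str
    value: float
    effect_year: Optional[int] = None


@dataclass
class ScheduleSet:
    """All evaluated parameter schedules for one projection run."""

    enrolment: dict[str, Schedule]
    graduation: dict[str, Schedule]
    entry: dict[str, Schedule]
    attrition_voluntary: dict[str, Schedule]
    attrition_involuntary: dict[str, Schedule]
    immigration: dict[str, Schedule]

    def attrition_total(self, class_id: str, year: int) -> float:
        return (self.attrition_voluntary[class_id].value(year)
                + self.attrition_involuntary[class_id].value(year))


def compile_schedules(config: ModelConfig,
                      overrides: Sequence[Override] = ()) -> ScheduleSet:
    """Resolve overrides against a configuration into per-parameter schedules.

    Later overrides of the same parameter win.  Out-of-range values raise
    :class:`~hrhsim.params.ConfigError`; entry rates above 1 are tolerated so
    that solvers can sweep a combined graduation x entry product through the
    entry rate.
    """
    sched = ScheduleSet(
        enrolment={p.id: constant_schedule(p.annual_enrolment)
                   for p in config.programs},
        graduation={p.id: constant_schedule(p.graduation_rate)
                    for p in config.programs},
        entry={p.id: constant_schedule(p.entry_rate) for p in config.programs},
        attrition_voluntary={c.id: constant_schedule(c.attrition_voluntary)
                             for c in config.stock_classes},
        attrition_involuntary={c.id: constant_schedule(c.attrition_involuntary)
                               for c in config.stock_classes},
        immigration={c.id: constant_schedule(c.immigration)
                     for c in config.stock_classes},
    )
    class_ids = {c.id for c in config.stock_classes}
    program_ids = {p.id for p in config.programs}
    start = config.baseline_year

    for ov in overrides:
        effect = config.baseline_year + 2 if ov.effect_year is None \
            else int(ov.effect_year)
        if effect < start:
            raise ConfigError(
                f"override {ov.path!r}: effect year {effect} precedes "
                f"baseline year {start}")
        parts = ov.path.split(".")
        head, rest = parts[0], parts[1:]
        v1 = float(ov.value)
        if head in class_ids:
            if rest == ["attrition", "total"]:
                if not 0.0 <= v1 < 1.0:
                    raise ConfigError(f"{ov.path}: rate {v1} outside [0, 1)")
                c = config.stock_class(head)
                if c.attrition_total > 0:
                    scale = v1 / c.attrition_total
                    vol1 = c.attrition_voluntary * scale
                    invol1 = c.attrition_involuntary * scale
                else:
                    # no split to preserve: assign the new total per the
                    # reporting shares
                    vol1 = v1 * config.attrition_report_shares[2]
                    invol1 = v1 - vol1
                sched.attrition_voluntary[head] = build_schedule(
                    c.attrition_voluntary, vol1, start, effect)
                sched.attrition_involuntary[head] = build_schedule(
                    c.attrition_involuntary, invol1, start, effect)
            elif rest == ["attrition", "voluntary"]:
                if not 0.0 <= v1 < 1.0:
                    raise ConfigError(f"{ov.path}: rate {v1} outside [0, 1)")
                c = config.stock_class(head)
                sched.attrition_voluntary[head] = build_schedule(
                    c.attrition_voluntary, v1, start, effect)
            elif rest == ["immigration"]:
                if v1 < 0:
                    raise ConfigError(f"{ov.path}: immigration must be >= 0")
                c = config.stock_class(head)
                sched.immigration[head] = build_schedule(
                    c.immigration, v1, start, effect)
            else:
                raise ConfigError(
                    f"override path {ov.path!r}: unknown stock-class field")
        elif head in program_ids:
            p = config.program(head)
            if rest == ["enrolment"]:
                if v1 < 0:
                    raise ConfigError(f"{ov.path}: enrolment must be >= 0")
                sched.enrolment[head] = build_schedule(
                    p.annual_enrolment, v1, start, effect)
            elif rest == ["enrolment_multiplier"]:
                if v1 < 0:
                    raise ConfigError(f"{ov.path}: multiplier must be >= 0")
                sched.enrolment[head] = build_schedule(
                    p.annual_enrolment, p.annual_enrolment * v1, start, effect)
            elif rest == ["graduation_rate"]:
                if not 0.0 <= v1 <= 1.0:
                    raise ConfigError(f"{ov.path}: rate {v1} outside [0, 1]")
                sched.graduation[head] = build_schedule(
                    p.graduation_rate, v1, start, effect)
            elif rest == ["entry_rate"]:
                if v1 < 0:
                    raise ConfigError(f"{ov.path}: entry rate must be >= 0")
                sched.entry[head] = build_schedule(
                    p.entry_rate, v1, start, effect)
            else:
                raise ConfigError(
                    f"override path {ov.path!r}: unknown program field")
        else:
            raise ConfigError(
                f"override path {ov.path!r}: {head!r} is neither a stock "
                f"class nor a program id")
    return sched
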