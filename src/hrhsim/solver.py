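"""Policy solvers: equilibrium enrolment, minimum enrolment multipliers,
and the attrition x graduation-entry multiplier grid.

*Equilibrium enrolment* answers "once a cadre sits at its staffing target,
what annual enrolment keeps it there?" -- hires plus immigration must
balance attrition plus back-to-school exits at the target stock:

    sum_p w_p * E * g_p * p_p  =  a * T + S_eq - m

with the requirement allocated across a cadre's programs in proportion to
their baseline enrolments (weights ``w_p``).  Back-to-school exits at
equilibrium depend on the *destination* cadres' equilibrium enrolments, so
the system is solved as a fixed point across cadres.

*Minimum enrolment multiplier* answers "by what factor must a cadre's
training enrolment grow (ramped in by the effect year) so the cadre reaches
its target at the horizon?"  The horizon stock is monotone in the
multiplier, so the smallest sufficient factor is found by bisection; both
the continuous factor and its integer ceiling are reported, along with the
implied annual enrolment (rounded up -- a fractional student cannot be
enrolled).

*Multiplier grid* repeats the multiplier solve over a mesh of attrition
rates and combined graduation x entry rates, reproducing the standard
policy heat-map: how much less enrolment growth is needed if retention or
training throughput improve.
"""

from __future__ import annotations

import contextlib
import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .params import ModelConfig
from .schedules import Override
from .engine import run_projection

__all__ = ["InfeasibleError", "EquilibriumResult", "MultiplierResult",
           "GridResult", "equilibrium_enrolment", "min_enrolment_multiplier",
           "multiplier_grid"]

_BISECTION_TOL = 1e-6
_MULTIPLIER_CEILING = 1000.0


class InfeasibleError(RuntimeError):
    """No admissible enrolment satisfies the requirement."""


@dataclass(frozen=True)
class EquilibriumResult:
    """Annual enrolment sustaining a cadre exactly at its target."""

    cadre_id: str
    enrolment_by_program: dict[str, float]   # continuous students/yr
    total_enrolment: float

    @property
    def total_enrolment_int(self) -> int:
        """Whole students per year (rounded up)."""
        return math.ceil(self.total_enrolment - 1e-9)


@dataclass(frozen=True)
class MultiplierResult:
    """Smallest enrolment multiplier reaching the target by the horizon."""

    cadre_id: str
    multiplier: float                        # continuous
    multiplier_int: int                      # ceiling
    enrolment_by_program: dict[str, float]   # continuous, at the multiplier
    required_enrolment: dict[str, int]       # ceiling per program
    achieved_stock: float                    # horizon stock at multiplier_int
    feasible: bool = True


@dataclass(frozen=True)
class GridResult:
    """Integer multipliers over an attrition x graduation-entry mesh."""

    cadre_id: str
    attrition_values: tuple[float, ...]      # rows
    grad_entry_values: tuple[float, ...]     # columns
    multipliers: np.ndarray                  # int matrix; -1 = infeasible


def _cadre_weights(config: ModelConfig, cadre_id: str) -> dict[str, float]:
    """Baseline enrolment shares of a cadre's programs (equal if all zero)."""
    progs = config.programs_into_cadre(cadre_id)
    if not progs:
        return {}
    total = sum(p.annual_enrolment for p in progs)
    if total > 0:
        return {p.id: p.annual_enrolment / total for p in progs}
    return {p.id: 1.0 / len(progs) for p in progs}


def _target_attrition_outflow(config: ModelConfig, cadre_id: str) -> float:
    """Annual attrition exits with the cadre held at its target.

    The target head-count is allocated across member classes in proportion
    to baseline stocks (equally if the cadre starts empty) since classes may
    carry different attrition rates.
    """
    k = config.cadre(cadre_id)
    members = [config.stock_class(m) for m in k.member_classes]
    base_total = sum(c.baseline_stock for c in members)
    out = 0.0
    for c in members:
        share = c.baseline_stock / base_total if base_total > 0 \
            else 1.0 / len(members)
        out += c.attrition_total * k.target_stock * share
    return out


def equilibrium_enrolment(config: ModelConfig,
                          cadre_id: str) -> EquilibriumResult:
    """Annual enrolment at which hires exactly replace exits at the target.

    Solved jointly for all cadres (feeder links couple them through
    back-to-school exits) by fixed-point iteration, then reported for the
    requested cadre.
    """
    config.cadre(cadre_id)  # validate the id early
    cadres = [k.id for k in config.reporting_cadres]
    weights = {kid: _cadre_weights(config, kid) for kid in cadres}
    attrition_out = {kid: _target_attrition_outflow(config, kid)
                     for kid in cadres}
    immigration = {
        kid: sum(config.stock_class(m).immigration
                 for m in config.cadre(kid).member_classes)
        for kid in cadres}
    cadre_of_program = {p.id: config.stock_class(p.output_class).reporting_cadre
                        for p in config.programs}
    member_sets = {kid: set(config.cadre(kid).member_classes)
                   for kid in cadres}

    totals = {kid: sum(p.annual_enrolment
                       for p in config.programs_into_cadre(kid))
              for kid in cadres}
    for _ in range(500):
        new_totals = {}
        for kid in cadres:
            school = sum(
                p.feeder.fraction * weights[cadre_of_program[p.id]][p.id]
                * totals[cadre_of_program[p.id]]
                for p in config.programs
                if p.feeder is not None
                and p.feeder.source_class in member_sets[kid])
            required_hires = attrition_out[kid] + school - immigration[kid]
            denom = sum(w * config.program(pid).graduation_rate
                        * config.program(pid).entry_rate
                        for pid, w in weights[kid].items())
            if required_hires <= 0:
                new_totals[kid] = 0.0
            elif denom <= 0:
                raise InfeasibleError(
                    f"cadre {kid}: positive hire requirement but zero "
                    f"graduation x entry throughput")
            else:
                new_totals[kid] = required_hires / denom
        if max(abs(new_totals[kid] - totals[kid]) for kid in cadres) < 1e-12:
            totals = new_totals
            break
        totals = new_totals

    per_program = {pid: w * totals[cadre_id]
                   for pid, w in weights[cadre_id].items()}
    return EquilibriumResult(cadre_id=cadre_id,
                             enrolment_by_program=per_program,
                             total_enrolment=totals[cadre_id])


def _scenario_overrides(config: ModelConfig, cadre_id: str,
                        attrition: Optional[float],
                        grad_entry: Optional[float],
                        effect_year: Optional[int]) -> list[Override]:
    """Ramped attrition / combined-rate overrides for one cadre.

    The combined graduation x entry product is swept through the entry rate
    with the graduation rate untouched; horizon stocks depend on the two
    rates only through their product under this model's timing, so the
    choice is immaterial (asserted by a property test).
    """
    overrides: list[Override] = []
    if attrition is not None:
        for m in config.cadre(cadre_id).member_classes:
            overrides.append(Override(f"{m}.attrition.total", attrition,
                                      effect_year))
    if grad_entry is not None:
        for p in config.programs_into_cadre(cadre_id):
            if p.graduation_rate <= 0:
                raise InfeasibleError(
                    f"program {p.id}: cannot express combined rate "
                    f"{grad_entry} through a zero graduation rate")
            overrides.append(Override(f"{p.id}.entry_rate",
                                      grad_entry / p.graduation_rate,
                                      effect_year))
    return overrides


def min_enrolment_multiplier(config: ModelConfig, cadre_id: str,
                             attrition: Optional[float] = None,
                             grad_entry: Optional[float] = None,
                             effect_year: Optional[int] = None
                             ) -> MultiplierResult:
    """Smallest enrolment factor that lifts the cadre to its target.

    The factor applies to every program of the cadre, ramped in like any
    scenario (midpoint in the intermediate year, full value from the effect
    year).  Bisection on the continuous factor to 1e-6; the horizon stock is
    monotone in the factor, making the bracket valid.
    """
    target = config.cadre(cadre_id).target_stock
    base_overrides = _scenario_overrides(config, cadre_id, attrition,
                                         grad_entry, effect_year)
    progs = config.programs_into_cadre(cadre_id)

    def horizon_stock(x: float) -> float:
        overrides = base_overrides + [
            Override(f"{p.id}.enrolment_multiplier", x, effect_year)
            for p in progs]
        # bisection probes extreme multipliers on purpose; the engine's
        # clamp warnings about drained feeder classes are expected there
        engine_log = logging.getLogger("hrhsim.engine")
        old_level = engine_log.level
        engine_log.setLevel(logging.ERROR)
        try:
            traj = run_projection(config, overrides, capping=False)
        finally:
            engine_log.setLevel(old_level)
        return traj.cadre_stocks(cadre_id)[-1]

    def result(x: float, feasible: bool = True) -> MultiplierResult:
        x_int = max(1, math.ceil(x - 1e-9))
        enrol = {p.id: x * p.annual_enrolment for p in progs}
        required = {pid: math.ceil(e - 1e-9) for pid, e in enrol.items()}
        return MultiplierResult(
            cadre_id=cadre_id, multiplier=x, multiplier_int=x_int,
            enrolment_by_program=enrol, required_enrolment=required,
            achieved_stock=horizon_stock(float(x_int)), feasible=feasible)

    if horizon_stock(1.0) >= target:
        return result(1.0)
    if horizon_stock(_MULTIPLIER_CEILING) < target:
        return result(_MULTIPLIER_CEILING, feasible=False)
    lo, hi = 1.0, _MULTIPLIER_CEILING
    while hi - lo > _BISECTION_TOL:
        mid = 0.5 * (lo + hi)
        if horizon_stock(mid) >= target:
            hi = mid
        else:
            lo = mid
    return result(hi)


def multiplier_grid(config: ModelConfig, cadre_id: str,
                    attrition_values: Sequence[float],
                    grad_entry_values: Sequence[float],
                    effect_year: Optional[int] = None) -> GridResult:
    """Integer enrolment multipliers over an attrition x grad-entry mesh."""
    for a in attrition_values:
        if not 0.0 <= a < 1.0:
            raise ValueError(f"attrition value {a} outside [0, 1)")
    for gp in grad_entry_values:
        if not 0.0 <= gp <= 1.0:
            raise ValueError(f"grad-entry value {gp} outside [0, 1]")
    matrix = np.zeros((len(attrition_values), len(grad_entry_values)),
                      dtype=int)
    for i, a in enumerate(attrition_values):
        for j, gp in enumerate(grad_entry_values):
            res = min_enrolment_multiplier(config, cadre_id, attrition=a,
                                           grad_entry=gp,
                                           effect_year=effect_year)
            matrix[i, j] = res.multiplier_int if res.feasible else -1
    return GridResult(cadre_id=cadre_id,
                      attrition_values=tuple(float(a) for a in attrition_values),
                      grad_entry_values=tuple(float(g) for g in grad_entry_values),
                      multipliers=matrix)
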