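"""Annual stock-and-flow projection with a lagged training pipeline.

The state of the model in year ``Y`` is the head-count ``N_c(Y)`` of every
stock class plus the cohorts currently in training.  One transition
``Y -> Y+1`` proceeds, per class, as

    N(Y+1) = (N(Y) - S(Y+1)) * (1 - a(Y)) + H(Y+1) + m(Y+1)

where ``S`` is the back-to-school outflow (members leaving to join cohorts
that enrol in year ``Y+1``, removed before attrition is applied), ``a(Y)``
the attrition rate in force during year ``Y``, ``H`` the hires from training
and ``m`` the inflow from abroad.  A cohort that enrols in year ``e`` in a
program of duration ``d`` is hired in year ``e + d + 1``:

    H(Y) = cohort(Y - d - 1) * g(Y - 1) * p(Y - 1)

with the graduation rate ``g`` and public-sector entry rate ``p`` of the
year preceding the hire.  The pipeline is pre-filled at the baseline
enrolment so hires flow at the steady-state rate from the first projected
year (the model assumes the training system was already running at its
baseline throughput before the projection starts).

Stocks are continuous; rounding to whole persons happens only when results
are formatted for reports.

Target capping
--------------
When enabled, a reporting cadre's stock is never allowed to exceed its
staffing target: the engine reduces the enrolment of the cohorts feeding an
overshooting hire year (a look-ahead of ``d + 1`` years), allocating the
reduction across the cadre's programs in proportion to their planned
enrolments.  Because a smaller cohort also means fewer workers leaving a
feeder class for school in the cohort's enrolment year -- which lies
*before* the capped hire year -- the whole trajectory is resolved by
fixed-point iteration on the realized enrolments (tolerance 1e-9; the
feeder links form a DAG, so a handful of passes suffice).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .params import ModelConfig, ProgramSpec
from .schedules import Schedule, ScheduleSet, compile_schedules

__all__ = ["PipelineUnderflowError", "ConvergenceError", "Trajectory",
           "init_pipeline", "annual_hires", "school_outflow", "step",
           "run_projection"]

logger = logging.getLogger(__name__)

#: cohort sizes per program, keyed ``program id -> enrolment year -> students``
PipelineState = dict[str, dict[int, float]]


class PipelineUnderflowError(RuntimeError):
    """A hire year referenced a cohort that was never initialized."""


class ConvergenceError(RuntimeError):
    """The capping fixed point failed to converge (non-DAG feeders?)."""


def _init_cohorts(config: ModelConfig, sched: ScheduleSet,
                  end_year: int) -> PipelineState:
    state: PipelineState = {}
    for p in config.programs:
        first = config.baseline_year - p.duration_years
        state[p.id] = {e: max(0.0, sched.enrolment[p.id].value(e))
                       for e in range(first, end_year + 1)}
    return state


def init_pipeline(config: ModelConfig,
                  schedules: Optional[ScheduleSet] = None) -> PipelineState:
    """Cohorts for every enrolment year the projection can reference.

    For each program the map covers enrolment years from
    ``baseline_year - duration`` through ``horizon_year``.  Pre-baseline
    cohorts are synthetic: they are filled at the baseline annual enrolment
    (a schedule evaluates to its baseline value before the ramp starts), so
    that programs -- including those whose output class starts empty --
    deliver steady-state hires from the first projected year onward.
    """
    sched = schedules if schedules is not None else compile_schedules(config)
    return _init_cohorts(config, sched, config.horizon_year)


def annual_hires(pipeline: PipelineState, program: ProgramSpec,
                 grad_schedule: Schedule, entry_schedule: Schedule,
                 year: int) -> float:
    """Hires a program delivers into the workforce in ``year``.

    The cohort that enrolled ``duration + 1`` years earlier graduates and is
    hired, thinned by the graduation and entry rates of the prior year.
    """
    e = year - program.duration_years - 1
    try:
        cohort = pipeline[program.id][e]
    except KeyError:
        raise PipelineUnderflowError(
            f"program {program.id}: no cohort for enrolment year {e} "
            f"(hire year {year}); pipeline not initialized far enough back")
    return cohort * grad_schedule.value(year - 1) * entry_schedule.value(year - 1)


def school_outflow(programs: Sequence[ProgramSpec],
                   enrolments: Mapping[str, Mapping[int, float] | Schedule],
                   year: int) -> dict[str, float]:
    """Workforce exits into training cohorts enrolling in ``year``, per class.

    Each feeder-linked program pulls ``fraction x enrolment(year)`` serving
    members out of its source class; the outflow scales with the destination
    program's (possibly scenario-modified or cap-reduced) enrolment.
    """
    out: dict[str, float] = {}
    for q in programs:
        if q.feeder is None:
            continue
        source = enrolments[q.id]
        value = source.value(year) if isinstance(source, Schedule) \
            else source[year]
        out[q.feeder.source_class] = out.get(q.feeder.source_class, 0.0) \
            + q.feeder.fraction * value
    return out


@dataclass
class Trajectory:
    """Per-year stocks and categorized flows of one projection run.

    Stock arrays are indexed by simulation year (``years[i]``); flow arrays
    hold the flow realized during the transition *into* ``years[i]`` (index
    0, the baseline year, is all zeros).  ``enrolments`` holds the realized
    cohort sizes, including synthetic pre-baseline cohorts and any
    cap-induced reductions (also tabulated in ``enrolment_reductions``).
    """

    config: ModelConfig
    years: np.ndarray
    stocks: dict[str, np.ndarray]
    hires: dict[str, np.ndarray]
    immigration: dict[str, np.ndarray]
    school_outflow: dict[str, np.ndarray]
    attrition_retire: dict[str, np.ndarray]
    attrition_involuntary: dict[str, np.ndarray]
    attrition_voluntary: dict[str, np.ndarray]
    hires_by_program: dict[str, np.ndarray]
    cohort_by_program: dict[str, np.ndarray]
    grad_by_program: dict[str, np.ndarray]
    entry_by_program: dict[str, np.ndarray]
    enrolments: PipelineState
    capped: dict[str, np.ndarray]
    enrolment_reductions: dict[str, dict[int, float]]

    def year_index(self, year: int) -> int:
        i = int(year) - int(self.years[0])
        if not 0 <= i < len(self.years):
            raise KeyError(f"year {year} outside simulated range "
                           f"{self.years[0]}..{self.years[-1]}")
        return i

    def stock(self, class_id: str, year: int) -> float:
        return float(self.stocks[class_id][self.year_index(year)])

    def cadre_stocks(self, cadre_id: str) -> np.ndarray:
        members = self.config.cadre(cadre_id).member_classes
        return np.sum([self.stocks[m] for m in members], axis=0)

    def cadre_stock(self, cadre_id: str, year: int) -> float:
        return float(self.cadre_stocks(cadre_id)[self.year_index(year)])

    def combined_stocks(self) -> np.ndarray:
        return np.sum([self.stocks[c.id] for c in self.config.stock_classes],
                      axis=0)

    def attrition_total(self, class_id: str) -> np.ndarray:
        return (self.attrition_retire[class_id]
                + self.attrition_involuntary[class_id]
                + self.attrition_voluntary[class_id])

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per year x stock class."""
        rows = []
        for c in self.config.stock_classes:
            for i, y in enumerate(self.years):
                rows.append({
                    "year": int(y),
                    "stock_class": c.id,
                    "stock": self.stocks[c.id][i],
                    "hires": self.hires[c.id][i],
                    "immigration": self.immigration[c.id][i],
                    "attrition_retire": self.attrition_retire[c.id][i],
                    "attrition_involuntary": self.attrition_involuntary[c.id][i],
                    "attrition_voluntary": self.attrition_voluntary[c.id][i],
                    "school_outflow": self.school_outflow[c.id][i],
                })
        return pd.DataFrame(rows)


def step(stocks: Mapping[str, float], pipeline: PipelineState,
         config: ModelConfig, schedules: ScheduleSet,
         year: int) -> dict[str, float]:
    """One uncapped transition from ``year`` to ``year + 1``.

    Convenience wrapper over the update rule for single-step inspection;
    :func:`run_projection` performs the same arithmetic internally.
    """
    if year >= config.horizon_year:
        raise ValueError(f"cannot step beyond horizon year {config.horizon_year}")
    nxt = year + 1
    outflow = school_outflow(config.programs,
                             {pid: schedules.enrolment[pid]
                              for pid in pipeline}, nxt)
    new: dict[str, float] = {}
    for c in config.stock_classes:
        hires = sum(
            annual_hires(pipeline, p, schedules.graduation[p.id],
                         schedules.entry[p.id], nxt)
            for p in config.programs_into_class(c.id))
        base = stocks[c.id] - outflow.get(c.id, 0.0)
        if base < 0:
            logger.warning("%s: stock driven negative by school outflow in "
                           "%d; clamped at 0", c.id, nxt)
            base = 0.0
        a = schedules.attrition_total(c.id, year)
        value = base * (1.0 - a) + hires + schedules.immigration[c.id].value(nxt)
        new[c.id] = max(value, 0.0)
    return new


def _simulate_pass(config: ModelConfig, sched: ScheduleSet,
                   outflow_enrol: PipelineState, capping: bool,
                   end_year: Optional[int] = None
                   ) -> tuple[Trajectory, PipelineState]:
    """One forward pass; returns the trajectory and realized enrolments.

    School outflows are computed from ``outflow_enrol`` (the previous
    fixed-point iterate) while hires and cap reductions operate on a fresh
    copy of the planned enrolments.  ``end_year`` may extend the simulation
    past the horizon (used by the capped run so that cohorts hired after the
    horizon are still subject to the anticipatory cap); the returned
    trajectory is truncated to the reporting range.
    """
    end_year = config.horizon_year if end_year is None else end_year
    years = np.arange(config.baseline_year, end_year + 1)
    n = len(years)
    n_report = config.horizon_year - config.baseline_year + 1
    class_ids = [c.id for c in config.stock_classes]
    prog_ids = [p.id for p in config.programs]

    enrol = _init_cohorts(config, sched, end_year)

    def zeros_for(ids):
        return {i: np.zeros(n) for i in ids}

    stocks = zeros_for(class_ids)
    hires_cls = zeros_for(class_ids)
    immigration = zeros_for(class_ids)
    school = zeros_for(class_ids)
    att_ret = zeros_for(class_ids)
    att_inv = zeros_for(class_ids)
    att_vol = zeros_for(class_ids)
    hires_prog = zeros_for(prog_ids)
    cohort_prog = zeros_for(prog_ids)
    grad_prog = zeros_for(prog_ids)
    entry_prog = zeros_for(prog_ids)
    capped = {k.id: np.zeros(n, dtype=bool) for k in config.reporting_cadres}

    for c in config.stock_classes:
        stocks[c.id][0] = c.baseline_stock

    ret_share, inv_other_share, _vol_share = config.attrition_report_shares
    inv_total_share = ret_share + inv_other_share
    programs_of_class = {cid: config.programs_into_class(cid)
                         for cid in class_ids}

    for i in range(1, n):
        y = int(years[i])
        prev = y - 1

        outflow = school_outflow(config.programs, outflow_enrol, y)

        grads = {pid: sched.graduation[pid].value(prev) for pid in prog_ids}
        entries = {pid: sched.entry[pid].value(prev) for pid in prog_ids}
        cohorts: dict[str, float] = {}
        hires_p: dict[str, float] = {}
        for p in config.programs:
            e = y - p.duration_years - 1
            if e not in enrol[p.id]:
                raise PipelineUnderflowError(
                    f"program {p.id}: missing cohort for enrolment year {e}")
            cohorts[p.id] = enrol[p.id][e]
            hires_p[p.id] = cohorts[p.id] * grads[p.id] * entries[p.id]

        base: dict[str, float] = {}
        att: dict[str, float] = {}
        new: dict[str, float] = {}
        rates: dict[str, tuple[float, float]] = {}
        for c in config.stock_classes:
            b = stocks[c.id][i - 1] - outflow.get(c.id, 0.0)
            if b < -1e-9:
                logger.warning("%s: school outflow exceeds stock in %d; "
                               "clamped at 0", c.id, y)
            b = max(b, 0.0)
            a_vol = sched.attrition_voluntary[c.id].value(prev)
            a_inv = sched.attrition_involuntary[c.id].value(prev)
            rates[c.id] = (a_vol, a_inv)
            base[c.id] = b
            att[c.id] = b * (a_vol + a_inv)
            h = sum(hires_p[p.id] for p in programs_of_class[c.id])
            m = sched.immigration[c.id].value(y)
            value = b - att[c.id] + h + m
            if value < 0:
                logger.warning("%s: stock driven negative in %d; clamped at 0",
                               c.id, y)
                value = 0.0
            new[c.id] = value
            immigration[c.id][i] = m

        if capping:
            for k in config.reporting_cadres:
                total = sum(new[m] for m in k.member_classes)
                excess = total - k.target_stock
                if excess <= 1e-12:
                    continue
                progs = [p for p in config.programs
                         if p.output_class in k.member_classes]
                denom = sum(hires_p[p.id] for p in progs)
                if denom <= 0:
                    logger.warning(
                        "cadre %s exceeds its target in %d but no cohort "
                        "feeds that year; cannot cap", k.id, y)
                    continue
                # shrink the feeding cohorts in proportion to their planned
                # enrolments, i.e. uniformly, by the factor that removes the
                # excess hires exactly (clamped so cohorts stay >= 0)
                mu = min(1.0, excess / denom)
                for p in progs:
                    e = y - p.duration_years - 1
                    reduction = mu * enrol[p.id][e]
                    enrol[p.id][e] -= reduction
                    cohorts[p.id] = enrol[p.id][e]
                    hires_p[p.id] = cohorts[p.id] * grads[p.id] * entries[p.id]
                for m in k.member_classes:
                    h = sum(hires_p[p.id] for p in programs_of_class[m])
                    new[m] = max(base[m] - att[m] + h
                                 + immigration[m][i], 0.0)
                capped[k.id][i] = True
                if sum(new[m] for m in k.member_classes) \
                        > k.target_stock + 1e-9:
                    logger.warning(
                        "cadre %s still exceeds its target in %d after "
                        "zeroing all feeding cohorts", k.id, y)

        for c in config.stock_classes:
            a_vol, a_inv = rates[c.id]
            a = a_vol + a_inv
            vol_flow = att[c.id] * (a_vol / a) if a > 0 else 0.0
            inv_flow = att[c.id] - vol_flow
            retire = inv_flow * (ret_share / inv_total_share) \
                if inv_total_share > 0 else 0.0
            stocks[c.id][i] = new[c.id]
            hires_cls[c.id][i] = sum(hires_p[p.id]
                                     for p in programs_of_class[c.id])
            school[c.id][i] = outflow.get(c.id, 0.0)
            att_ret[c.id][i] = retire
            att_inv[c.id][i] = inv_flow - retire
            att_vol[c.id][i] = vol_flow
        for p in config.programs:
            hires_prog[p.id][i] = hires_p[p.id]
            cohort_prog[p.id][i] = cohorts[p.id]
            grad_prog[p.id][i] = grads[p.id]
            entry_prog[p.id][i] = entries[p.id]

    planned = _init_cohorts(config, sched, end_year)
    reductions = {
        pid: {e: planned[pid][e] - enrol[pid][e]
              for e in planned[pid]
              if planned[pid][e] - enrol[pid][e] > 1e-12}
        for pid in prog_ids}

    cut = slice(0, n_report)
    traj = Trajectory(
        config=config, years=years[cut],
        stocks={c: v[cut] for c, v in stocks.items()},
        hires={c: v[cut] for c, v in hires_cls.items()},
        immigration={c: v[cut] for c, v in immigration.items()},
        school_outflow={c: v[cut] for c, v in school.items()},
        attrition_retire={c: v[cut] for c, v in att_ret.items()},
        attrition_involuntary={c: v[cut] for c, v in att_inv.items()},
        attrition_voluntary={c: v[cut] for c, v in att_vol.items()},
        hires_by_program={p: v[cut] for p, v in hires_prog.items()},
        cohort_by_program={p: v[cut] for p, v in cohort_prog.items()},
        grad_by_program={p: v[cut] for p, v in grad_prog.items()},
        entry_by_program={p: v[cut] for p, v in entry_prog.items()},
        enrolments=enrol,
        capped={k: v[cut] for k, v in capped.items()},
        enrolment_reductions=reductions)
    return traj, enrol


def run_projection(config: ModelConfig, scenario=None,
                   capping: Optional[bool] = None) -> Trajectory:
    """Simulate from the baseline year to the horizon year.

    ``scenario`` may be ``None``, a sequence of
    :class:`~hrhsim.schedules.Override` or any object with an ``overrides``
    attribute (a :class:`~hrhsim.scenarios.ScenarioSpec`).  ``capping``
    overrides the configuration's ``capping_enabled`` flag.
    """
    overrides = getattr(scenario, "overrides", scenario)
    sched = compile_schedules(config, tuple(overrides or ()))
    do_cap = config.capping_enabled if capping is None else capping

    if not do_cap:
        planned = init_pipeline(config, sched)
        traj, _ = _simulate_pass(config, sched, planned, capping=False)
        return traj

    # the anticipatory cap must also govern cohorts whose hire year falls
    # just past the horizon -- otherwise enrolment (and the feeder outflow
    # it drives) would snap back to the scenario level near the window edge
    end_year = config.horizon_year + max(p.duration_years
                                         for p in config.programs) + 1 \
        if config.programs else config.horizon_year
    outflow_enrol = _init_cohorts(config, sched, end_year)
    for _ in range(100):
        traj, realized = _simulate_pass(config, sched, outflow_enrol,
                                        capping=True, end_year=end_year)
        diff = max(
            (abs(realized[pid][e] - outflow_enrol[pid][e])
             for pid in realized for e in realized[pid]),
            default=0.0)
        if diff < 1e-9:
            return traj
        outflow_enrol = {pid: dict(cohorts)
                         for pid, cohorts in realized.items()}
    raise ConvergenceError(
        "target capping did not reach a fixed point in 100 iterations")
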