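"""Window-aggregated flow ledgers and percent-of-target summaries.

The flow ledger decomposes the change in a cadre's stock over a year window
into the standard published accounting:

    inflow  = enrolled - failed_to_graduate - not_hired + from_abroad
    outflow = retirement + involuntary_other + voluntary + back_to_school
    final   = baseline + inflow - outflow

The inflow terms use *cohort-sourced* accounting: every hire year inside the
window is attributed back to the training cohort that produced it
(including synthetic pre-baseline cohorts), so "enrolled" counts the
students whose pipeline feeds the window's hires, not the students enrolling
during the window.  Retirement is reported as a carve-out of involuntary
attrition using the configured report shares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .params import ModelConfig
from .engine import Trajectory

__all__ = ["round_half_up", "FlowLedger", "decompose_flows",
           "attrition_split", "summarize_vs_target", "flow_ledger_frame",
           "write_flow_ledger_csv", "write_summary_csv"]


def round_half_up(x: float) -> int:
    """Round to the nearest integer, ties away from zero toward +inf."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class FlowLedger:
    """Inflow/outflow decomposition of one cadre over a year window."""

    cadre_id: str
    window: tuple[int, int]
    baseline_stock: float
    final_stock: float
    target: float
    enrolled: float            # a: students in the cohorts feeding the window
    failed: float              # b: of those, non-graduates
    not_hired: float           # c: graduates not entering the public sector
    immigration: float         # d: hired from abroad
    retire: float              # e
    involuntary_other: float   # f
    voluntary: float           # g
    school: float              # h: back-to-school leavers

    @property
    def inflow(self) -> float:
        return self.enrolled - self.failed - self.not_hired + self.immigration

    @property
    def outflow(self) -> float:
        return self.retire + self.involuntary_other + self.voluntary + self.school

    @property
    def net_gain(self) -> float:
        return self.inflow - self.outflow

    @property
    def remaining_gap(self) -> float:
        return self.target - round_half_up(self.final_stock)


def decompose_flows(trajectory: Trajectory, config: ModelConfig,
                    window: Optional[tuple[int, int]] = None
                    ) -> dict[str, FlowLedger]:
    """Flow ledger per reporting cadre plus a ``combined`` total.

    ``window=(y0, y1)`` aggregates the transitions into years
    ``y0+1 .. y1``; the default is the full simulated range.  A degenerate
    window ``(y, y)`` contains no transitions and yields all-zero flows.
    """
    y0, y1 = window if window is not None else (
        int(trajectory.years[0]), int(trajectory.years[-1]))
    if y1 < y0:
        raise ValueError(f"window {window} is reversed")
    i0 = trajectory.year_index(y0)
    i1 = trajectory.year_index(y1)
    sel = slice(i0 + 1, i1 + 1)  # transitions into years y0+1 .. y1

    ledgers: dict[str, FlowLedger] = {}
    for k in config.reporting_cadres:
        members = k.member_classes
        progs = [p for p in config.programs if p.output_class in members]
        enrolled = failed = not_hired = 0.0
        for p in progs:
            cohort = trajectory.cohort_by_program[p.id][sel]
            g = trajectory.grad_by_program[p.id][sel]
            pr = trajectory.entry_by_program[p.id][sel]
            enrolled += float(np.sum(cohort))
            failed += float(np.sum(cohort * (1.0 - g)))
            not_hired += float(np.sum(cohort * g * (1.0 - pr)))
        immigration = sum(float(np.sum(trajectory.immigration[m][sel]))
                          for m in members)
        retire = sum(float(np.sum(trajectory.attrition_retire[m][sel]))
                     for m in members)
        invol = sum(float(np.sum(trajectory.attrition_involuntary[m][sel]))
                    for m in members)
        vol = sum(float(np.sum(trajectory.attrition_voluntary[m][sel]))
                  for m in members)
        school = sum(float(np.sum(trajectory.school_outflow[m][sel]))
                     for m in members)
        ledgers[k.id] = FlowLedger(
            cadre_id=k.id, window=(y0, y1),
            baseline_stock=trajectory.cadre_stock(k.id, y0),
            final_stock=trajectory.cadre_stock(k.id, y1),
            target=k.target_stock,
            enrolled=enrolled, failed=failed, not_hired=not_hired,
            immigration=immigration, retire=retire,
            involuntary_other=invol, voluntary=vol, school=school)

    ledgers["combined"] = FlowLedger(
        cadre_id="combined", window=(y0, y1),
        baseline_stock=sum(l.baseline_stock for l in ledgers.values()),
        final_stock=sum(l.final_stock for l in ledgers.values()),
        target=sum(l.target for l in ledgers.values()),
        enrolled=sum(l.enrolled for l in ledgers.values()),
        failed=sum(l.failed for l in ledgers.values()),
        not_hired=sum(l.not_hired for l in ledgers.values()),
        immigration=sum(l.immigration for l in ledgers.values()),
        retire=sum(l.retire for l in ledgers.values()),
        involuntary_other=sum(l.involuntary_other for l in ledgers.values()),
        voluntary=sum(l.voluntary for l in ledgers.values()),
        school=sum(l.school for l in ledgers.values()))
    return ledgers


def attrition_split(total_attrition_flow: float,
                    shares: Sequence[float] = (0.10, 0.58, 0.32)
                    ) -> tuple[float, float, float]:
    """Split a total attrition flow into (retirement, involuntary-other,
    voluntary) components that sum to the input exactly."""
    if total_attrition_flow < 0:
        raise ValueError("attrition flow must be non-negative")
    if abs(sum(shares) - 1.0) > 1e-9:
        raise ValueError(f"shares {tuple(shares)} do not sum to 1")
    retire = total_attrition_flow * shares[0]
    invol = total_attrition_flow * shares[1]
    voluntary = total_attrition_flow - retire - invol
    return retire, invol, voluntary


def summarize_vs_target(trajectory: Trajectory, config: ModelConfig,
                        year: int) -> pd.DataFrame:
    """Per-cadre (and combined) stock, percent of target and remaining gap.

    Stocks are rounded half-up before the percentage (one decimal) and the
    gap are computed, matching report formatting.
    """
    i = trajectory.year_index(year)  # validates the year
    rows = []
    total_stock = 0.0
    total_target = 0.0
    for k in config.reporting_cadres:
        stock = trajectory.cadre_stock(k.id, year)
        total_stock += stock
        total_target += k.target_stock
        rounded = round_half_up(stock)
        rows.append({
            "cadre": k.id, "year": int(year), "stock": rounded,
            "target": k.target_stock,
            "pct": round_half_up(rounded / k.target_stock * 1000.0) / 10.0,
            "gap": k.target_stock - rounded,
        })
    rounded = round_half_up(total_stock)
    rows.append({
        "cadre": "combined", "year": int(year), "stock": rounded,
        "target": total_target,
        "pct": round_half_up(rounded / total_target * 1000.0) / 10.0,
        "gap": total_target - rounded,
    })
    return pd.DataFrame(rows)


_LEDGER_ROWS = [
    ("final_stock", "projected workforce ( = baseline + inflow - outflow)"),
    ("baseline_stock", "baseline workforce"),
    ("inflow", "inflow ( = a - b - c + d)"),
    ("enrolled", "a students that enrolled"),
    ("failed", "b students that failed to graduate"),
    ("not_hired", "c graduates not hired into public sector"),
    ("immigration", "d hired from abroad"),
    ("outflow", "outflow ( = e + f + g + h)"),
    ("retire", "e retire"),
    ("involuntary_other", "f involuntary attrition"),
    ("voluntary", "g voluntary attrition"),
    ("school", "h go back to school"),
    ("net_gain", "total gain or loss"),
    ("remaining_gap", "remaining staffing gap"),
]


def flow_ledger_frame(ledgers: dict[str, FlowLedger]) -> pd.DataFrame:
    """Wide report: rows are flow categories, columns cadres plus combined.

    Values are rounded half-up to whole persons (internal values stay
    continuous in the :class:`FlowLedger` objects).
    """
    columns = [cid for cid in ledgers if cid != "combined"] + ["combined"]
    data = {}
    for cid in columns:
        ledger = ledgers[cid]
        data[cid] = [round_half_up(getattr(ledger, attr))
                     for attr, _ in _LEDGER_ROWS]
    frame = pd.DataFrame(data, index=[label for _, label in _LEDGER_ROWS])
    frame.index.name = "flow"
    return frame


def write_flow_ledger_csv(ledgers: dict[str, FlowLedger],
                          path: str | Path) -> None:
    flow_ledger_frame(ledgers).to_csv(path, lineterminator="\r\n")


def write_summary_csv(summary: pd.DataFrame, path: str | Path) -> None:
    summary.to_csv(path, index=False, lineterminator="\r\n")
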