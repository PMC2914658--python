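"""What-if scenarios and the single-intervention comparison table.

A :class:`ScenarioSpec` is a named bundle of parameter overrides, each
ramped in linearly between the baseline year and its effect year (see
:mod:`hrhsim.schedules`).  :func:`single_variable_suite` runs the standard
one-at-a-time policy levers -- perfect graduation, perfect public-sector
entry, zero voluntary attrition, doubled and tripled training enrolment --
and tabulates the horizon-year stock of each reporting cadre against its
staffing target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .params import ConfigError, ModelConfig
from .schedules import Override

__all__ = ["ScenarioSpec", "parse_override", "run_scenario",
           "build_single_variable_scenarios", "single_variable_suite"]


@dataclass(frozen=True)
class ScenarioSpec:
    """A named list of overrides applied on top of the base configuration."""

    name: str
    overrides: tuple[Override, ...] = ()


def parse_override(text: str) -> Override:
    """Parse the CLI form ``path=value[@year]``.

    Examples: ``doctors.attrition.voluntary=0@2010``,
    ``medicine.enrolment_multiplier=2``.
    """
    if "=" not in text:
        raise ConfigError(f"override {text!r}: expected path=value[@year]")
    path, _, rhs = text.partition("=")
    effect: Optional[int] = None
    if "@" in rhs:
        rhs, _, year_text = rhs.partition("@")
        try:
            effect = int(year_text)
        except ValueError:
            raise ConfigError(f"override {text!r}: bad effect year "
                              f"{year_text!r}") from None
    try:
        value = float(rhs)
    except ValueError:
        raise ConfigError(f"override {text!r}: bad value {rhs!r}") from None
    return Override(path=path.strip(), value=value, effect_year=effect)


def run_scenario(config: ModelConfig, scenario: ScenarioSpec,
                 capping: Optional[bool] = None):
    """Project the workforce under a scenario's overrides."""
    from .engine import run_projection
    return run_projection(config, scenario, capping=capping)


def build_single_variable_scenarios(config: ModelConfig) -> list[ScenarioSpec]:
    """The standard one-at-a-time intervention set, baseline first."""
    every_program = [p.id for p in config.programs]
    every_class = [c.id for c in config.stock_classes]
    return [
        ScenarioSpec("baseline"),
        ScenarioSpec("graduation_rate_100pct", tuple(
            Override(f"{pid}.graduation_rate", 1.0) for pid in every_program)),
        ScenarioSpec("voluntary_attrition_0pct", tuple(
            Override(f"{cid}.attrition.voluntary", 0.0)
            for cid in every_class)),
        ScenarioSpec("entry_rate_100pct", tuple(
            Override(f"{pid}.entry_rate", 1.0) for pid in every_program)),
        ScenarioSpec("enrolment_x2", tuple(
            Override(f"{pid}.enrolment_multiplier", 2.0)
            for pid in every_program)),
        ScenarioSpec("enrolment_x3", tuple(
            Override(f"{pid}.enrolment_multiplier", 3.0)
            for pid in every_program)),
    ]


def single_variable_suite(config: ModelConfig,
                          capping: Optional[bool] = None) -> pd.DataFrame:
    """Horizon-year stocks and percent-of-target for each standard scenario.

    One row per scenario x reporting cadre, plus a ``combined`` row per
    scenario.  Stocks are rounded half-up to whole persons before the
    percentage is taken (to one decimal), so the table matches what a
    published report would print.
    """
    from .reporting import round_half_up

    horizon = config.horizon_year
    rows = []
    for spec in build_single_variable_scenarios(config):
        traj = run_scenario(config, spec, capping=capping)
        combined_stock = 0.0
        combined_target = 0.0
        for k in config.reporting_cadres:
            stock = traj.cadre_stock(k.id, horizon)
            combined_stock += stock
            combined_target += k.target_stock
            rounded = round_half_up(stock)
            pct = round_half_up(rounded / k.target_stock * 1000.0) / 10.0
            rows.append({"scenario": spec.name, "cadre": k.id,
                         f"stock_{horizon}": rounded, "pct_of_target": pct})
        rounded = round_half_up(combined_stock)
        pct = round_half_up(rounded / combined_target * 1000.0) / 10.0
        rows.append({"scenario": spec.name, "cadre": "combined",
                     f"stock_{horizon}": rounded, "pct_of_target": pct})
    return pd.DataFrame(rows)
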