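"""Model configuration: domain types, validation and file I/O.

A workforce model is described by three kinds of objects:

* :class:`StockClass` -- one workforce compartment (e.g. enrolled nurses)
  with its own baseline head-count, annual attrition rates and, optionally,
  an annual inflow of hires from abroad.
* :class:`ProgramSpec` -- a training program feeding one stock class, with a
  training duration, annual enrolment, graduation rate, public-sector entry
  rate and an optional *feeder* link: a fraction of each entering cohort is
  drawn out of an existing workforce class (nurses leaving to train as
  midwives, for instance).
* :class:`ReportingCadre` -- a group of stock classes that share a single
  staffing target; targets (and the anticipatory enrolment cap) apply to the
  summed stock of the member classes.

Configurations are stored as YAML following the schema documented in
``docs/config-schema.md``.  Unknown keys are rejected so that typos fail
fast rather than silently falling back to defaults.  The published Zambia
2008 parameter set ships with the package and is returned by
:func:`zambia_fixture`.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import yaml

__all__ = [
    "ConfigError",
    "SchemaError",
    "ValidationError",
    "Feeder",
    "StockClass",
    "ProgramSpec",
    "ReportingCadre",
    "ModelConfig",
    "load_config",
    "write_config",
    "zambia_fixture",
    "random_config",
    "write_trajectory_csv",
]


class ConfigError(ValueError):
    """Base class for configuration problems."""


class SchemaError(ConfigError):
    """The file does not match the documented schema (bad or unknown keys)."""


class ValidationError(ConfigError):
    """The file parsed but violates a model invariant."""


@dataclass(frozen=True)
class Feeder:
    """Link drawing a fraction of a program's enrolment out of the workforce.

    ``fraction`` of every entering cohort consists of serving members of
    ``source_class`` who leave employment to study; the induced exits scale
    with the destination program's (possibly scenario-modified) enrolment.
    """

    source_class: str
    fraction: float


@dataclass(frozen=True)
class StockClass:
    """One workforce compartment with its own attrition and immigration.

    Attrition rates are annual fractions of the pre-hire stock.  The
    voluntary/involuntary split must sum to ``attrition_total`` (the loader
    derives the total from the parts, so the invariant holds exactly).
    """

    id: str
    reporting_cadre: str
    baseline_stock: float
    attrition_total: float
    attrition_voluntary: float
    attrition_involuntary: float
    immigration: float = 0.0


@dataclass(frozen=True)
class ProgramSpec:
    """A training program: duration, enrolment, rates and feeder link.

    A cohort enrolling in year ``e`` studies for ``duration_years`` years and
    its surviving graduates are hired in year ``e + duration_years + 1`` (one
    hiring year after graduation).
    """

    id: str
    output_class: str
    duration_years: int
    annual_enrolment: float
    graduation_rate: float
    entry_rate: float
    feeder: Optional[Feeder] = None


@dataclass(frozen=True)
class ReportingCadre:
    """A group of stock classes sharing one staffing target (the cap unit)."""

    id: str
    member_classes: tuple[str, ...]
    target_stock: float


@dataclass(frozen=True)
class ModelConfig:
    """A complete, validated workforce model.

    ``attrition_report_shares`` is the (retirement, involuntary-other,
    voluntary) decomposition of total attrition used when reporting flow
    ledgers; retirement is a carve-out of the involuntary component.
    """

    baseline_year: int
    horizon_year: int
    stock_classes: tuple[StockClass, ...]
    programs: tuple[ProgramSpec, ...]
    reporting_cadres: tuple[ReportingCadre, ...]
    attrition_report_shares: tuple[float, float, float] = (0.10, 0.58, 0.32)
    capping_enabled: bool = True

    # -- lookup helpers -------------------------------------------------

    def stock_class(self, class_id: str) -> StockClass:
        for c in self.stock_classes:
            if c.id == class_id:
                return c
        raise KeyError(f"unknown stock class {class_id!r}")

    def program(self, program_id: str) -> ProgramSpec:
        for p in self.programs:
            if p.id == program_id:
                return p
        raise KeyError(f"unknown program {program_id!r}")

    def cadre(self, cadre_id: str) -> ReportingCadre:
        for k in self.reporting_cadres:
            if k.id == cadre_id:
                return k
        raise KeyError(f"unknown reporting cadre {cadre_id!r}")

    def cadre_of_class(self, class_id: str) -> ReportingCadre:
        return self.cadre(self.stock_class(class_id).reporting_cadre)

    def programs_into_class(self, class_id: str) -> tuple[ProgramSpec, ...]:
        return tuple(p for p in self.programs if p.output_class == class_id)

    def programs_into_cadre(self, cadre_id: str) -> tuple[ProgramSpec, ...]:
        members = set(self.cadre(cadre_id).member_classes)
        return tuple(p for p in self.programs if p.output_class in members)

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.baseline_year, self.horizon_year + 1)


# ----------------------------------------------------------------------
# validation


def _check_rate(name: str, value: float, lo: float = 0.0, hi: float = 1.0,
                hi_open: bool = False) -> None:
    bad = value < lo or (value >= hi if hi_open else value > hi)
    if bad:
        bracket = f"[{lo}, {hi}" + (")" if hi_open else "]")
        raise ValidationError(f"{name} = {value} outside {bracket}")


def validate_config(config: ModelConfig) -> ModelConfig:
    """Check every model invariant; return the config unchanged if valid."""
    if config.horizon_year <= config.baseline_year:
        raise ValidationError(
            f"horizon_year {config.horizon_year} must exceed baseline_year "
            f"{config.baseline_year}")
    shares = config.attrition_report_shares
    if len(shares) != 3 or any(s < 0 for s in shares):
        raise ValidationError("attrition_report_shares must be 3 non-negative values")
    if abs(sum(shares) - 1.0) > 1e-6:
        raise ValidationError(
            f"attrition_report_shares sum to {sum(shares)}, expected 1.0")

    class_ids = [c.id for c in config.stock_classes]
    if len(set(class_ids)) != len(class_ids):
        raise ValidationError("duplicate stock class ids")
    program_ids = [p.id for p in config.programs]
    if len(set(program_ids)) != len(program_ids):
        raise ValidationError("duplicate program ids")
    cadre_ids = [k.id for k in config.reporting_cadres]
    if len(set(cadre_ids)) != len(cadre_ids):
        raise ValidationError("duplicate reporting cadre ids")
    if set(class_ids) & set(program_ids):
        raise ValidationError("stock class and program ids must not collide")

    for c in config.stock_classes:
        if c.baseline_stock < 0:
            raise ValidationError(f"{c.id}: baseline_stock must be non-negative")
        if c.immigration < 0:
            raise ValidationError(f"{c.id}: immigration must be non-negative")
        _check_rate(f"{c.id}.attrition_voluntary", c.attrition_voluntary)
        _check_rate(f"{c.id}.attrition_involuntary", c.attrition_involuntary)
        _check_rate(f"{c.id}.attrition_total", c.attrition_total, hi_open=True)
        if abs(c.attrition_voluntary + c.attrition_involuntary
               - c.attrition_total) > 1e-9:
            raise ValidationError(
                f"{c.id}: voluntary + involuntary attrition != total")
        if c.reporting_cadre not in cadre_ids:
            raise ValidationError(
                f"{c.id}: unknown reporting cadre {c.reporting_cadre!r}")

    for p in config.programs:
        if p.output_class not in class_ids:
            raise ValidationError(
                f"program {p.id}: unknown output class {p.output_class!r}")
        if not (isinstance(p.duration_years, (int, np.integer))
                and p.duration_years >= 1):
            raise ValidationError(
                f"program {p.id}: duration_years must be an integer >= 1")
        if p.annual_enrolment < 0:
            raise ValidationError(
                f"program {p.id}: annual_enrolment must be non-negative")
        _check_rate(f"{p.id}.graduation_rate", p.graduation_rate)
        _check_rate(f"{p.id}.entry_rate", p.entry_rate)
        if p.feeder is not None:
            if p.feeder.source_class not in class_ids:
                raise ValidationError(
                    f"program {p.id}: unknown feeder source "
                    f"{p.feeder.source_class!r}")
            _check_rate(f"{p.id}.feeder.fraction", p.feeder.fraction)

    # member lists must partition the stock classes and agree with the
    # per-class cadre assignment
    seen: dict[str, str] = {}
    for k in config.reporting_cadres:
        if k.target_stock <= 0:
            raise ValidationError(f"cadre {k.id}: target_stock must be > 0")
        for m in k.member_classes:
            if m not in class_ids:
                raise ValidationError(f"cadre {k.id}: unknown member {m!r}")
            if m in seen:
                raise ValidationError(
                    f"class {m} listed in cadres {seen[m]} and {k.id}")
            seen[m] = k.id
            if config.stock_class(m).reporting_cadre != k.id:
                raise ValidationError(
                    f"class {m}: reporting_cadre disagrees with cadre "
                    f"member list {k.id}")
    missing = set(class_ids) - set(seen)
    if missing:
        raise ValidationError(
            f"classes not covered by any reporting cadre: {sorted(missing)}")

    # feeder links must form a DAG over stock classes
    edges: dict[str, set[str]] = {c: set() for c in class_ids}
    for p in config.programs:
        if p.feeder is not None:
            edges[p.feeder.source_class].add(p.output_class)
    state: dict[str, int] = {}

    def visit(node: str, trail: list[str]) -> None:
        state[node] = 1
        for nxt in edges[node]:
            if state.get(nxt) == 1:
                raise ValidationError(
                    f"feeder links form a cycle through {' -> '.join(trail + [nxt])}")
            if state.get(nxt, 0) == 0:
                visit(nxt, trail + [nxt])
        state[node] = 2

    for node in class_ids:
        if state.get(node, 0) == 0:
            visit(node, [node])

    return config


# ----------------------------------------------------------------------
# YAML loading / writing

_TOP_KEYS = {"baseline_year", "horizon_year", "capping_enabled",
             "attrition_report_shares", "stock_classes", "programs",
             "reporting_cadres"}
_CLASS_KEYS = {"id", "reporting_cadre", "baseline_stock", "attrition",
               "immigration"}
_ATTRITION_KEYS = {"total", "voluntary", "involuntary"}
_PROGRAM_KEYS = {"id", "output_class", "duration_years", "annual_enrolment",
                 "graduation_rate", "entry_rate", "feeder"}
_FEEDER_KEYS = {"source_class", "fraction"}
_CADRE_KEYS = {"id", "members", "target_stock"}
_SHARE_KEYS = {"retirement", "involuntary_other", "voluntary"}


def _expect_mapping(obj, where: str) -> dict:
    if not isinstance(obj, dict):
        raise SchemaError(f"{where}: expected a mapping, got {type(obj).__name__}")
    return obj


def _check_keys(mapping: dict, allowed: set, required: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise SchemaError(f"{where}: unknown key(s) {sorted(unknown)}")
    missing = required - set(mapping)
    if missing:
        raise SchemaError(f"{where}: missing required key(s) {sorted(missing)}")


def _parse_attrition(raw, shares: tuple[float, float, float],
                     where: str) -> tuple[float, float, float]:
    """Return (total, voluntary, involuntary) from an attrition mapping.

    The split may be given directly, or only the total with the split taken
    from the report shares; when both forms are present they must agree to
    1e-6.  The stored total is always the exact sum of the parts.
    """
    raw = _expect_mapping(raw, where)
    _check_keys(raw, _ATTRITION_KEYS, set(), where)
    has_split = "voluntary" in raw and "involuntary" in raw
    if has_split:
        vol = float(raw["voluntary"])
        invol = float(raw["involuntary"])
        if "total" in raw and abs(float(raw["total"]) - (vol + invol)) > 1e-6:
            raise ValidationError(
                f"{where}: total attrition {raw['total']} disagrees with "
                f"voluntary + involuntary = {vol + invol}")
    elif "total" in raw:
        total = float(raw["total"])
        vol_share = shares[2]
        vol = total * vol_share
        invol = total - vol
    else:
        raise SchemaError(
            f"{where}: give either 'total' or both 'voluntary' and 'involuntary'")
    return vol + invol, vol, invol


def config_from_dict(raw: dict) -> ModelConfig:
    """Build and validate a :class:`ModelConfig` from parsed YAML data."""
    raw = _expect_mapping(raw, "config")
    _check_keys(raw, _TOP_KEYS,
                {"baseline_year", "horizon_year", "stock_classes",
                 "programs", "reporting_cadres"}, "config")

    shares_raw = raw.get("attrition_report_shares")
    if shares_raw is None:
        shares = (0.10, 0.58, 0.32)
    else:
        shares_raw = _expect_mapping(shares_raw, "attrition_report_shares")
        _check_keys(shares_raw, _SHARE_KEYS, _SHARE_KEYS,
                    "attrition_report_shares")
        shares = (float(shares_raw["retirement"]),
                  float(shares_raw["involuntary_other"]),
                  float(shares_raw["voluntary"]))

    classes = []
    for entry in raw["stock_classes"] or []:
        entry = _expect_mapping(entry, "stock_classes[]")
        where = f"stock_classes[{entry.get('id', '?')}]"
        _check_keys(entry, _CLASS_KEYS,
                    {"id", "reporting_cadre", "baseline_stock", "attrition"},
                    where)
        total, vol, invol = _parse_attrition(entry["attrition"], shares,
                                             f"{where}.attrition")
        classes.append(StockClass(
            id=str(entry["id"]),
            reporting_cadre=str(entry["reporting_cadre"]),
            baseline_stock=float(entry["baseline_stock"]),
            attrition_total=total,
            attrition_voluntary=vol,
            attrition_involuntary=invol,
            immigration=float(entry.get("immigration", 0.0)),
        ))

    programs = []
    for entry in raw["programs"] or []:
        entry = _expect_mapping(entry, "programs[]")
        where = f"programs[{entry.get('id', '?')}]"
        _check_keys(entry, _PROGRAM_KEYS,
                    {"id", "output_class", "duration_years",
                     "annual_enrolment", "graduation_rate", "entry_rate"},
                    where)
        feeder = None
        if entry.get("feeder") is not None:
            fraw = _expect_mapping(entry["feeder"], f"{where}.feeder")
            _check_keys(fraw, _FEEDER_KEYS, _FEEDER_KEYS, f"{where}.feeder")
            feeder = Feeder(source_class=str(fraw["source_class"]),
                            fraction=float(fraw["fraction"]))
        duration = entry["duration_years"]
        if isinstance(duration, float) and not duration.is_integer():
            raise ValidationError(f"{where}: duration_years must be an integer")
        programs.append(ProgramSpec(
            id=str(entry["id"]),
            output_class=str(entry["output_class"]),
            duration_years=int(duration),
            annual_enrolment=float(entry["annual_enrolment"]),
            graduation_rate=float(entry["graduation_rate"]),
            entry_rate=float(entry["entry_rate"]),
            feeder=feeder,
        ))

    cadres = []
    for entry in raw["reporting_cadres"] or []:
        entry = _expect_mapping(entry, "reporting_cadres[]")
        where = f"reporting_cadres[{entry.get('id', '?')}]"
        _check_keys(entry, _CADRE_KEYS, _CADRE_KEYS, where)
        members = entry["members"]
        if not isinstance(members, list):
            raise SchemaError(f"{where}.members: expected a list")
        cadres.append(ReportingCadre(
            id=str(entry["id"]),
            member_classes=tuple(str(m) for m in members),
            target_stock=float(entry["target_stock"]),
        ))

    config = ModelConfig(
        baseline_year=int(raw["baseline_year"]),
        horizon_year=int(raw["horizon_year"]),
        stock_classes=tuple(classes),
        programs=tuple(programs),
        reporting_cadres=tuple(cadres),
        attrition_report_shares=shares,
        capping_enabled=bool(raw.get("capping_enabled", True)),
    )
    return validate_config(config)


def config_to_dict(config: ModelConfig) -> dict:
    """Inverse of :func:`config_from_dict` (round-trips field-for-field)."""
    return {
        "baseline_year": int(config.baseline_year),
        "horizon_year": int(config.horizon_year),
        "capping_enabled": bool(config.capping_enabled),
        "attrition_report_shares": {
            "retirement": config.attrition_report_shares[0],
            "involuntary_other": config.attrition_report_shares[1],
            "voluntary": config.attrition_report_shares[2],
        },
        "stock_classes": [
            {
                "id": c.id,
                "reporting_cadre": c.reporting_cadre,
                "baseline_stock": c.baseline_stock,
                "attrition": {"voluntary": c.attrition_voluntary,
                              "involuntary": c.attrition_involuntary},
                "immigration": c.immigration,
            }
            for c in config.stock_classes
        ],
        "programs": [
            {
                "id": p.id,
                "output_class": p.output_class,
                "duration_years": int(p.duration_years),
                "annual_enrolment": p.annual_enrolment,
                "graduation_rate": p.graduation_rate,
                "entry_rate": p.entry_rate,
                **({"feeder": {"source_class": p.feeder.source_class,
                               "fraction": p.feeder.fraction}}
                   if p.feeder is not None else {}),
            }
            for p in config.programs
        ],
        "reporting_cadres": [
            {
                "id": k.id,
                "members": list(k.member_classes),
                "target_stock": k.target_stock,
            }
            for k in config.reporting_cadres
        ],
    }


def load_config(path: str | Path) -> ModelConfig:
    """Load and validate a model configuration from a YAML file."""
    text = Path(path).read_text(encoding="utf-8")
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise SchemaError(f"{path}: not valid YAML: {exc}") from exc
    return config_from_dict(raw)


def write_config(config: ModelConfig, path: str | Path) -> None:
    """Write a configuration as YAML; ``load_config`` restores it exactly."""
    Path(path).write_text(
        yaml.safe_dump(config_to_dict(config), sort_keys=False,
                       default_flow_style=False),
        encoding="utf-8")


def zambia_fixture() -> ModelConfig:
    """The published Zambia 2008 parameter set (7 classes, 7 programs, 4 cadres)."""
    source = importlib.resources.files("hrhsim.data").joinpath("zambia_2008.yaml")
    raw = yaml.safe_load(source.read_text(encoding="utf-8"))
    return config_from_dict(raw)


# ----------------------------------------------------------------------
# random configurations for property tests


def random_config(seed: int, n_classes: int, *,
                  allow_feeders: bool = True) -> ModelConfig:
    """Generate a reproducible random valid configuration.

    One stock class, one program and one reporting cadre per index.  Feeder
    links, when enabled, only point from lower to higher class indices and
    only from classes whose own program has no feeder, so chains are one
    level deep and acyclic by construction.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    rng = np.random.default_rng(seed)
    classes, programs, cadres = [], [], []
    has_feeder: list[bool] = []
    for i in range(n_classes):
        cid = f"class_{i}"
        total = float(rng.uniform(0.0, 0.15))
        vol = 0.32 * total
        invol = total - vol
        baseline = float(np.round(rng.uniform(0.0, 5000.0), 3))
        immigration = float(np.round(rng.uniform(0.0, 50.0), 3)) \
            if rng.random() < 0.3 else 0.0
        classes.append(StockClass(
            id=cid, reporting_cadre=f"cadre_{i}", baseline_stock=baseline,
            attrition_total=vol + invol, attrition_voluntary=vol,
            attrition_involuntary=invol, immigration=immigration))
        feeder = None
        if allow_feeders and i > 0 and rng.random() < 0.35:
            candidates = [j for j in range(i) if not has_feeder[j]]
            if candidates:
                j = int(rng.choice(candidates))
                feeder = Feeder(source_class=f"class_{j}",
                                fraction=float(rng.uniform(0.0, 1.0)))
        has_feeder.append(feeder is not None)
        programs.append(ProgramSpec(
            id=f"program_{i}", output_class=cid,
            duration_years=int(rng.integers(1, 8)),
            annual_enrolment=float(np.round(rng.uniform(0.0, 1000.0), 3)),
            graduation_rate=float(rng.uniform(0.5, 1.0)),
            entry_rate=float(rng.uniform(0.5, 1.0)),
            feeder=feeder))
        cadres.append(ReportingCadre(
            id=f"cadre_{i}", member_classes=(cid,),
            target_stock=float(np.round(baseline + rng.uniform(1.0, 5000.0), 3))))
    config = ModelConfig(
        baseline_year=2008,
        horizon_year=2008 + int(rng.integers(5, 15)),
        stock_classes=tuple(classes),
        programs=tuple(programs),
        reporting_cadres=tuple(cadres),
        capping_enabled=False,
    )
    return validate_config(config)


# ----------------------------------------------------------------------
# trajectory CSV output

TRAJECTORY_COLUMNS = ["year", "stock_class", "stock", "hires", "immigration",
                      "attrition_retire", "attrition_involuntary",
                      "attrition_voluntary", "school_outflow"]


def write_trajectory_csv(trajectory, path: str | Path) -> None:
    """Write one row per year x stock class at full floating precision.

    ``trajectory`` is any object with a ``to_frame`` method returning the
    standard long-format frame (see :meth:`hrhsim.engine.Trajectory.to_frame`).
    """
    frame = trajectory.to_frame()
    if frame.empty:
        raise ValueError("cannot write an empty trajectory")
    if list(frame.columns) != TRAJECTORY_COLUMNS:
        raise ValueError(f"unexpected trajectory columns: {list(frame.columns)}")
    frame.to_csv(path, index=False, lineterminator="\r\n")
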