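"""Configuration files, time-series output and named experiment fixtures.

The configuration format is nested YAML mirroring the parameter dataclasses;
any field may be overridden, unknown keys are an error. Time series are
written as plain CSV with a fixed column order and 12 significant digits, so
a write/read round trip reproduces the trajectory and identical configs
produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .core import (
    CUM_LABELS,
    SimulationResult,
    SolverSettings,
    simulate,
    simulate_one_compartment,
)
from .dosing import DoseEvent, Regimen
from .metrics import assess_toxicity, route_fractions
from .parameters import (
    GshParams,
    KineticParams,
    MetabolicPathway,
    Physiology,
    ScenarioConstants,
    TissueCompartment,
    default_kinetics,
    default_physiology,
)
from .scenarios import SCENARIO_NAMES, ScenarioModifiers, build_scenario

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "save_config",
    "config_to_dict",
    "config_from_dict",
    "write_timeseries",
    "read_timeseries",
    "LoadedTimeseries",
    "summarize",
    "write_summary",
    "generate_fixture",
    "FIXTURE_NAMES",
]


class ConfigError(ValueError):
    """Malformed or unknown configuration content."""


def _check_keys(d: dict, allowed: tuple[str, ...], context: str) -> None:
    unknown = set(d) - set(allowed)
    if unknown:
        raise ConfigError(f"unknown key(s) in {context}: {', '.join(sorted(unknown))}")


def _from_fields(cls, d: dict, context: str, **extra):
    names = tuple(f.name for f in dataclasses.fields(cls))
    _check_keys(d, names, context)
    return cls(**{**d, **extra})


@dataclass
class RunConfig:
    """A complete, resolvable description of one simulation run."""

    physiology: Physiology = field(default_factory=default_physiology)
    kinetics: KineticParams = field(default_factory=default_kinetics)
    regimen: Regimen = field(default_factory=lambda: Regimen.single(1.0))
    scenario_name: str = "normal"
    t_end_min: float = 1440.0
    settings: SolverSettings = field(default_factory=SolverSettings)
    model: str = "full"  # or "one-compartment" (analytic cross-check config)
    ka_per_min: float | None = None
    driving: str = "outflow"
    qss_napqi: bool = False
    seed: int | None = None  # reserved; the model is deterministic
    name: str = "run"

    def scenario(self) -> ScenarioModifiers:
        dose = self.regimen.dose_g
        if dose is None and self.regimen.events:
            dose = self.regimen.events[0].amount_g
        return build_scenario(self.scenario_name, dose, self.kinetics)

    def run(self) -> SimulationResult:
        if self.model != "full":
            raise ConfigError("RunConfig.run() requires the full model; "
                              "use run_one_compartment() for the collapsed config")
        return simulate(self.regimen, self.t_end_min, physiology=self.physiology,
                        kinetics=self.kinetics, scenario=self.scenario(),
                        settings=self.settings, driving=self.driving,
                        qss_napqi=self.qss_napqi, ka_per_min=self.ka_per_min)

    def run_one_compartment(self) -> tuple[np.ndarray, np.ndarray]:
        """Collapsed single-blood-pool run with first-order renal clearance."""
        blood_l = sum(self.physiology.by_name(n).volume_ml
                      for n in ("arterial_blood", "venous_blood")) / 1000.0
        cl = self.kinetics.renal_extraction \
            * self.physiology.by_name("kidney").blood_flow_ml_min / 1000.0
        return simulate_one_compartment(self.regimen, self.t_end_min, blood_l, cl,
                                        self.kinetics, self.settings)


# ---------------------------------------------------------------------------
# dict <-> dataclass conversion (strict about unknown keys)
# ---------------------------------------------------------------------------

def config_to_dict(cfg: RunConfig) -> dict[str, Any]:
    d = dataclasses.asdict(cfg)
    d["physiology"]["compartments"] = [dataclasses.asdict(c)
                                       for c in cfg.physiology.compartments]
    d["kinetics"]["pathways"] = [dataclasses.asdict(p) for p in cfg.kinetics.pathways]
    reg = d["regimen"]
    if cfg.regimen.is_periodic:
        reg.pop("events")
    else:
        for k in ("dose_g", "interval_min", "n_doses"):
            reg.pop(k)
        reg.pop("route")
        reg["events"] = [dataclasses.asdict(e) for e in cfg.regimen.events]
    return d


def _physiology_from_dict(d: dict) -> Physiology:
    _check_keys(d, ("compartments", "body_weight_kg", "blood_plasma_ratio"), "physiology")
    base = default_physiology()
    comps = base.compartments
    if "compartments" in d:
        comps = tuple(_from_fields(TissueCompartment, c, f"compartment #{i}")
                      for i, c in enumerate(d["compartments"]))
    return Physiology(
        compartments=comps,
        body_weight_kg=float(d.get("body_weight_kg", base.body_weight_kg)),
        blood_plasma_ratio=float(d.get("blood_plasma_ratio", base.blood_plasma_ratio)),
    )


def _kinetics_from_dict(d: dict) -> KineticParams:
    _check_keys(d, ("pathways", "renal_extraction", "oral_bioavailability",
                    "gsh", "scenario_constants", "apap_molar_mass"), "kinetics")
    base = default_kinetics()
    pathways = base.pathways
    if "pathways" in d:
        pathways = tuple(_from_fields(MetabolicPathway, p, f"pathway #{i}")
                         for i, p in enumerate(d["pathways"]))
    gsh = base.gsh
    if "gsh" in d:
        names = tuple(f.name for f in dataclasses.fields(GshParams))
        _check_keys(d["gsh"], names, "kinetics.gsh")
        gsh = dataclasses.replace(base.gsh, **d["gsh"])
    sc = base.scenario_constants
    if "scenario_constants" in d:
        names = tuple(f.name for f in dataclasses.fields(ScenarioConstants))
        _check_keys(d["scenario_constants"], names, "kinetics.scenario_constants")
        sc = dataclasses.replace(base.scenario_constants, **d["scenario_constants"])
    return KineticParams(
        pathways=pathways,
        renal_extraction=float(d.get("renal_extraction", base.renal_extraction)),
        oral_bioavailability=float(d.get("oral_bioavailability", base.oral_bioavailability)),
        gsh=gsh, scenario_constants=sc,
        apap_molar_mass=float(d.get("apap_molar_mass", base.apap_molar_mass)),
    )


def _regimen_from_dict(d: dict) -> Regimen:
    _check_keys(d, ("events", "dose_g", "interval_min", "n_doses", "route"), "regimen")
    if "events" in d:
        events = tuple(_from_fields(DoseEvent, e, f"dose event #{i}")
                       for i, e in enumerate(d["events"]))
        return Regimen(events=events)
    return Regimen.periodic(float(d["dose_g"]), float(d.get("interval_min", 360.0)),
                            int(d.get("n_doses", 1)), d.get("route", "oral"))


def config_from_dict(d: dict[str, Any]) -> RunConfig:
    _check_keys(d, ("physiology", "kinetics", "regimen", "scenario_name",
                    "t_end_min", "settings", "model", "ka_per_min", "driving",
                    "qss_napqi", "seed", "name"), "config")
    cfg = RunConfig()
    if "physiology" in d:
        cfg.physiology = _physiology_from_dict(d["physiology"])
    if "kinetics" in d:
        cfg.kinetics = _kinetics_from_dict(d["kinetics"])
    if "regimen" in d:
        cfg.regimen = _regimen_from_dict(d["regimen"])
    if "settings" in d:
        cfg.settings = _from_fields(SolverSettings, d["settings"], "settings")
    cfg.scenario_name = d.get("scenario_name", cfg.scenario_name)
    if cfg.scenario_name not in SCENARIO_NAMES:
        raise ConfigError(f"unknown scenario {cfg.scenario_name!r}; "
                          f"valid: {SCENARIO_NAMES}")
    cfg.t_end_min = float(d.get("t_end_min", cfg.t_end_min))
    cfg.model = d.get("model", cfg.model)
    if cfg.model not in ("full", "one-compartment"):
        raise ConfigError(f"unknown model {cfg.model!r}")
    ka = d.get("ka_per_min", cfg.ka_per_min)
    cfg.ka_per_min = None if ka is None else float(ka)
    cfg.driving = d.get("driving", cfg.driving)
    cfg.qss_napqi = bool(d.get("qss_napqi", cfg.qss_napqi))
    cfg.seed = d.get("seed", cfg.seed)
    cfg.name = d.get("name", cfg.name)
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping (file {path})")
    return config_from_dict(data)


# ---------------------------------------------------------------------------
# Time-series CSV
# ---------------------------------------------------------------------------

_TRACE_COLS = ("co_g", "co_s", "co_ox", "kgen_mult")


def timeseries_frame(result: SimulationResult) -> pd.DataFrame:
    """Fixed-column-order data frame of one trajectory."""
    data: dict[str, np.ndarray] = {"time_min": result.time}
    for j, name in enumerate(result.compartment_names):
        data[name] = result.conc[:, j]
    data["gsh_mmolL"] = result.gsh
    data["napqi_mmolL"] = result.napqi
    for j, label in enumerate(CUM_LABELS):
        data[f"cum_{label}"] = result.cum[:, j]
    for col in _TRACE_COLS:
        data[col] = result.traces[col]
    return pd.DataFrame(data)


def write_timeseries(result: SimulationResult, path: str | Path) -> None:
    """Write the trajectory as CSV (comma, dot decimal, 12 significant digits)."""
    timeseries_frame(result).to_csv(path, index=False, float_format="%.12g")


@dataclass
class LoadedTimeseries:
    """Trajectory re-read from CSV; enough for all trajectory metrics."""

    time: np.ndarray
    gsh: np.ndarray
    napqi: np.ndarray
    cum: np.ndarray
    frame: pd.DataFrame

    def cum_route(self, label: str) -> np.ndarray:
        return self.cum[:, CUM_LABELS.index(label)]


def read_timeseries(path: str | Path) -> LoadedTimeseries:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # pandas reports the offending line
        raise ConfigError(f"malformed time-series file {path}: {exc}") from exc
    required = ["time_min", "gsh_mmolL", "napqi_mmolL"] + \
        [f"cum_{label}" for label in CUM_LABELS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigError(f"time-series file {path} lacks column(s): {missing}")
    cum = df[[f"cum_{label}" for label in CUM_LABELS]].to_numpy()
    return LoadedTimeseries(
        time=df["time_min"].to_numpy(), gsh=df["gsh_mmolL"].to_numpy(),
        napqi=df["napqi_mmolL"].to_numpy(), cum=cum, frame=df,
    )


# ---------------------------------------------------------------------------
# Summary JSON
# ---------------------------------------------------------------------------

def summarize(result: SimulationResult) -> dict[str, Any]:
    """Headline numbers of one run (thresholds, routes, plasma Cmax/Tmax)."""
    tox = assess_toxicity(result)
    plasma = result.plasma()
    i_max = int(np.argmax(plasma))
    routes = route_fractions(result)
    return {
        "min_gsh_fraction": tox.min_gsh_fraction,
        "time_of_min_gsh_min": tox.time_of_min,
        "toxic": tox.toxic,
        "first_crossing_time_min": tox.first_crossing_time,
        "toxicity_fraction": tox.toxicity_fraction,
        "route_fractions": routes.as_dict(),
        "plasma_cmax_mmolL": float(plasma[i_max]),
        "plasma_tmax_min": float(result.time[i_max]),
        "absorbed_mmol": result.absorbed_mmol,
        "mass_balance_error": result.mass_balance_error(),
    }


def write_summary(result: SimulationResult, path: str | Path) -> dict[str, Any]:
    summary = summarize(result)
    Path(path).write_text(json.dumps(summary, indent=2) + "\n")
    return summary


# ---------------------------------------------------------------------------
# Named experiment fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = (
    "validation-iv-1g",
    "chronic-1g",
    "chronic-2g",
    "chronic-5g",
    "alcohol-therapeutic",
    "fasting-4g",
    "combined",
    "toy-one-compartment",
)


def generate_fixture(name: str) -> RunConfig:
    """The exact configuration of each named experiment.

    ``chronic-*``: 6-hourly oral dosing for 5 days with the dose-dependent
    induction schedule; ``alcohol-therapeutic``: therapeutic dosing starting
    when drinking stops; ``fasting-4g``: a single mild overdose in a
    malnourished subject; ``combined``: a chronic user (2 g per dose,
    supra-therapeutic) just after a binge; ``toy-one-compartment``: the
    collapsed analytic-oracle configuration.
    """
    if name == "validation-iv-1g":
        return RunConfig(regimen=Regimen.single(1.0, route="iv"),
                         scenario_name="normal", t_end_min=720.0, name=name)
    if name in ("chronic-1g", "chronic-2g", "chronic-5g"):
        dose = float(name.split("-")[1].rstrip("g"))
        return RunConfig(regimen=Regimen.periodic(dose, 360.0, 20, route="oral"),
                         scenario_name="chronic", t_end_min=7200.0, name=name)
    if name == "alcohol-therapeutic":
        return RunConfig(regimen=Regimen.periodic(1.0, 360.0, 20, route="oral"),
                         scenario_name="alcohol", t_end_min=7200.0, name=name)
    if name == "fasting-4g":
        return RunConfig(regimen=Regimen.single(4.0, route="oral"),
                         scenario_name="fasting", t_end_min=2880.0, name=name)
    if name == "combined":
        return RunConfig(regimen=Regimen.periodic(2.0, 360.0, 20, route="oral"),
                         scenario_name="chronic+alcohol", t_end_min=7200.0, name=name)
    if name == "toy-one-compartment":
        return RunConfig(regimen=Regimen.single(1.0, route="iv"),
                         scenario_name="normal", t_end_min=720.0,
                         model="one-compartment", name=name)
    raise ConfigError(f"unknown fixture {name!r}; valid names: {FIXTURE_NAMES}")
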