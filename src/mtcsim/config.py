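"""YAML run configuration: schema validation and unit conversion.

Configs are flat key-value sections (``muscle``, ``tendon``, ``load``,
``sim``, ``sweep``, ``synth``). All values are SI, except that for
readability the modulus may be given in GPa, lengths in cm, masses in g,
areas in mm2 and delays in ms via ``_gpa`` / ``_cm`` / ``_g`` / ``_mm2`` /
``_ms`` key suffixes; these are converted on load. Unknown keys are
rejected with the offending key named.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .muscle import ActivationCurve, MuscleSpec
from .simulate import SimConfig
from .sweep import Axis, SweepSpec
from .synth import SyntheticTruth, default_activation_curve
from .tendon_load import LoadSpec, TendonSpec

__all__ = ["ConfigError", "RunConfig", "load_config", "dump_muscle_section"]


class ConfigError(ValueError):
    """Schema violation in a run configuration."""


# section -> canonical key -> {accepted key: multiplier into SI}
_SCHEMA = {
    "muscle": {
        "max_isometric_stress": {"max_isometric_stress": 1.0,
                                 "max_isometric_stress_kpa": 1e3},
        "mass": {"mass": 1.0, "mass_g": 1e-3},
        "rest_length": {"rest_length": 1.0, "rest_length_cm": 1e-2},
        "density": {"density": 1.0},
        "hill_a_rel": {"hill_a_rel": 1.0},
        "hill_b": {"hill_b": 1.0},
        "reporting_vmax": {"reporting_vmax": 1.0},
        "normalize_active_fl": {"normalize_active_fl": None},
        "active_fl_coeffs": {"active_fl_coeffs": None},
        "passive_fl_coeffs": {"passive_fl_coeffs": None},
        "activation_csv": {"activation_csv": None},
    },
    "tendon": {
        "youngs_modulus": {"youngs_modulus": 1.0, "youngs_modulus_gpa": 1e9},
        "rest_length": {"rest_length": 1.0, "rest_length_cm": 1e-2},
        "cross_sectional_area": {"cross_sectional_area": 1.0,
                                 "cross_sectional_area_mm2": 1e-6},
    },
    "load": {
        "mass": {"mass": 1.0, "mass_g": 1e-3},
        "gravity": {"gravity": 1.0},
        "catch_delay": {"catch_delay": 1.0, "catch_delay_ms": 1e-3},
    },
    "sim": {
        "dt": {"dt": 1.0},
        "max_time": {"max_time": 1.0},
        "initial_muscle_length_pct": {"initial_muscle_length_pct": None},
        "solver_tolerance": {"solver_tolerance": 1.0},
        "record_trace": {"record_trace": None},
    },
    "synth": {
        "tau": {"tau": 1.0},
        "power": {"power": None},
        "sigma_fl": {"sigma_fl": None},
        "sigma_fv": {"sigma_fv": None},
        "sigma_tetanus": {"sigma_tetanus": None},
    },
}

_AXIS_KEYS = {"parameter", "low", "high", "n", "spacing"}


def _parse_section(name: str, raw: dict) -> dict:
    schema = _SCHEMA[name]
    accepted = {alias: (canon, mult)
                for canon, aliases in schema.items()
                for alias, mult in aliases.items()}
    out: dict[str, Any] = {}
    for key, value in raw.items():
        if key not in accepted:
            raise ConfigError(f"unknown key {key!r} in section {name!r}")
        canon, mult = accepted[key]
        if canon in out:
            raise ConfigError(f"duplicate specification of {canon!r} "
                              f"in section {name!r}")
        if mult is not None:
            try:
                value = float(value) * mult
            except (TypeError, ValueError):
                raise ConfigError(f"key {key!r} in section {name!r} must "
                                  f"be numeric, got {value!r}") from None
        out[canon] = value
    return out


def _parse_axis(raw: dict, which: str) -> Axis:
    unknown = set(raw) - _AXIS_KEYS
    if unknown:
        raise ConfigError(f"unknown key {sorted(unknown)[0]!r} in {which}")
    try:
        return Axis(parameter=raw["parameter"], low=float(raw["low"]),
                    high=float(raw["high"]), n=int(raw.get("n", 100)),
                    spacing=raw.get("spacing", ""))
    except KeyError as err:
        raise ConfigError(f"{which} is missing required key {err}") from None
    except ValueError as err:
        raise ConfigError(f"invalid {which}: {err}") from None


@dataclass
class RunConfig:
    """Parsed configuration: concrete spec objects per section."""

    muscle: MuscleSpec = field(default_factory=MuscleSpec)
    tendon: TendonSpec = field(default_factory=lambda: TendonSpec(1.5e9))
    load: LoadSpec = field(default_factory=lambda: LoadSpec(0.485))
    sim: SimConfig = field(default_factory=SimConfig)
    sweep: Optional[SweepSpec] = None
    synth: Optional[SyntheticTruth] = None


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping of sections")
    known = set(_SCHEMA) | {"sweep"}
    for section in raw:
        if section not in known:
            raise ConfigError(f"unknown section {section!r}")

    mkw = _parse_section("muscle", raw.get("muscle", {}) or {})
    act_csv = mkw.pop("activation_csv", None)
    if act_csv is not None:
        mkw["activation"] = ActivationCurve.from_csv(
            path.parent / str(act_csv))
    for key in ("active_fl_coeffs", "passive_fl_coeffs"):
        if key in mkw:
            mkw[key] = tuple(float(c) for c in mkw[key])
    if "initial_muscle_length_pct" in (raw.get("sim") or {}):
        pass
    muscle = MuscleSpec(**mkw)

    tkw = _parse_section("tendon", raw.get("tendon", {}) or {})
    tendon = TendonSpec(**tkw) if tkw else TendonSpec(1.5e9)

    lkw = _parse_section("load", raw.get("load", {}) or {})
    load = LoadSpec(**lkw) if lkw else LoadSpec(0.485)

    skw = _parse_section("sim", raw.get("sim", {}) or {})
    if "initial_muscle_length_pct" in skw:
        skw["initial_muscle_length_pct"] = float(
            skw["initial_muscle_length_pct"])
    if "record_trace" in skw:
        skw["record_trace"] = bool(skw["record_trace"])
    sim = SimConfig(**skw)

    sweep = None
    if "sweep" in raw:
        sraw = dict(raw["sweep"] or {})
        unknown = set(sraw) - {"axis1", "axis2"}
        if unknown:
            raise ConfigError(f"unknown key {sorted(unknown)[0]!r} in "
                              f"section 'sweep'")
        if "axis1" not in sraw or "axis2" not in sraw:
            raise ConfigError("sweep section needs axis1 and axis2")
        sweep = SweepSpec(axis1=_parse_axis(sraw["axis1"], "sweep.axis1"),
                          axis2=_parse_axis(sraw["axis2"], "sweep.axis2"),
                          muscle=muscle, tendon=tendon, load=load,
                          sim=sim if not sim.record_trace
                          else SimConfig(**{**skw, "record_trace": False}))

    synth = None
    if "synth" in raw:
        synth = SyntheticTruth(**_parse_section("synth", raw["synth"] or {}))

    return RunConfig(muscle=muscle, tendon=tendon, load=load, sim=sim,
                     sweep=sweep, synth=synth)


def dump_muscle_section(muscle: MuscleSpec, path: str | Path,
                        activation_csv: Optional[str] = None) -> None:
    """Write a MuscleSpec back out as a config section (SI units)."""
    section = {
        "max_isometric_stress": muscle.max_isometric_stress,
        "mass": muscle.mass,
        "rest_length": muscle.rest_length,
        "density": muscle.density,
        "hill_a_rel": muscle.hill_a_rel,
        "hill_b": muscle.hill_b,
        "reporting_vmax": muscle.reporting_vmax,
        "active_fl_coeffs": [float(c) for c in muscle.active_fl_coeffs],
        "passive_fl_coeffs": [float(c) for c in muscle.passive_fl_coeffs],
    }
    if activation_csv is not None:
        section["activation_csv"] = activation_csv
    with open(path, "w") as fh:
        yaml.safe_dump({"muscle": section}, fh, sort_keys=False)
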