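"""Configuration loading, validation, and run manifests.

Config files are YAML with sections ``magnet``, ``flow``, ``channel``,
``particle``, ``sim`` and ``materials``.  All internal quantities are SI;
scalar values may be given as strings with a unit suffix (``"50 nm"``,
``"0.4 cm"``, ``"0.1 ms"``) which are converted on load.  Unknown keys are
rejected, and all validation problems are reported together.

An empty config resolves to the full default run: bare Fe3O4 core in the
4 mm channel at 0.10 m/s mean pulsatile flow, with the implanted magnet
calibrated to 0.5 T and 180 T/m at the vessel centre.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import re
from dataclasses import replace
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .hemodynamics import (ChannelGeometry, FlowWaveform, ViscosityParams,
                           WaveformLandmarks, make_waveform)
from .magnetics import MagnetSpec, calibrate_to_target
from .particles import MATERIALS, Material, ParticleSpec
from .transport import SimulationConfig

__all__ = [
    "ConfigError",
    "load_config",
    "default_config",
    "dump_config",
    "RunManifest",
]

_VERSION = "0.1.0"

_UNIT_SCALE = {
    "m": 1.0, "cm": 1e-2, "mm": 1e-3, "um": 1e-6, "μm": 1e-6,
    "nm": 1e-9, "s": 1.0, "ms": 1e-3, "us": 1e-6, "T": 1.0, "mT": 1e-3,
    "T/m": 1.0, "T/cm": 100.0, "m/s": 1.0, "cm/s": 1e-2, "mm/s": 1e-3,
    "K": 1.0,
}


class ConfigError(ValueError):
    """Raised with the full list of config problems."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n  - "
                         + "\n  - ".join(self.problems))


def _parse_quantity(value: Any, key: str, problems: list[str]) -> float:
    """A bare number (SI) or a string with one of the known unit suffixes."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    if isinstance(value, str):
        m = re.fullmatch(r"\s*([-+0-9.eE]+)\s*([a-zA-Z/μ]*)\s*", value)
        if m:
            num, unit = m.groups()
            try:
                x = float(num)
            except ValueError:
                problems.append(f"{key}: cannot parse number in {value!r}")
                return float("nan")
            if unit == "":
                return x
            if unit in _UNIT_SCALE:
                return x * _UNIT_SCALE[unit]
            problems.append(f"{key}: unknown unit {unit!r}")
            return float("nan")
    problems.append(f"{key}: expected a number or 'value unit' string, "
                    f"got {value!r}")
    return float("nan")


def _check_keys(section: dict, allowed: set[str], prefix: str,
                problems: list[str]) -> None:
    for k in section:
        if k not in allowed:
            problems.append(f"unknown key {prefix}{k}")


def default_config(seed: int = 0, n_particles: int = 6000) -> SimulationConfig:
    """The full default run specification (see module docstring)."""
    cfg = SimulationConfig(seed=seed, n_particles=n_particles)
    target = (np.mean(cfg.geometry.magnet_footprint), cfg.geometry.width / 2)
    magnet = calibrate_to_target(cfg.magnet, target, 0.5, 180.0)
    return replace(cfg, magnet=magnet)


def load_config(path) -> SimulationConfig:
    """Load and validate a YAML run configuration."""
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text) or {}
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark else ""
        raise ConfigError([f"YAML parse error{where}: {exc}"]) from exc
    if not isinstance(raw, dict):
        raise ConfigError(["top level of the config must be a mapping"])
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> SimulationConfig:
    problems: list[str] = []
    _check_keys(raw, {"magnet", "flow", "channel", "particle", "sim",
                      "materials"}, "", problems)

    mats = dict(MATERIALS)
    for name, spec in (raw.get("materials") or {}).items():
        _check_keys(spec, {"density", "susceptibility", "viscosity"},
                    f"materials.{name}.", problems)
        try:
            mats[name] = Material(
                name, density=_parse_quantity(
                    spec.get("density"), f"materials.{name}.density",
                    problems),
                susceptibility=float(spec.get("susceptibility", 0.0)),
                viscosity=spec.get("viscosity"))
        except (TypeError, ValueError) as exc:
            problems.append(f"materials.{name}: {exc}")

    # channel ----------------------------------------------------------------
    ch = raw.get("channel") or {}
    _check_keys(ch, {"width", "length", "magnet_footprint", "blood_density"},
                "channel.", problems)
    geo_kwargs: dict[str, Any] = {}
    if "width" in ch:
        geo_kwargs["width"] = _parse_quantity(ch["width"], "channel.width",
                                              problems)
    if "length" in ch:
        geo_kwargs["length"] = _parse_quantity(ch["length"], "channel.length",
                                               problems)
    if "blood_density" in ch:
        geo_kwargs["blood_density"] = _parse_quantity(
            ch["blood_density"], "channel.blood_density", problems)
    if "magnet_footprint" in ch:
        fp = ch["magnet_footprint"]
        if not (isinstance(fp, (list, tuple)) and len(fp) == 2):
            problems.append("channel.magnet_footprint: expected [start, end]")
        else:
            geo_kwargs["magnet_footprint"] = tuple(
                _parse_quantity(v, "channel.magnet_footprint", problems)
                for v in fp)
    geometry = None
    if not problems:
        try:
            geometry = ChannelGeometry(**geo_kwargs)
        except ValueError as exc:
            problems.append(f"channel: {exc}")
    if geometry is None:
        try:
            geometry = ChannelGeometry(**{
                k: v for k, v in geo_kwargs.items() if np.isfinite(
                    np.asarray(v, dtype=float)).all()})
        except (TypeError, ValueError):
            geometry = ChannelGeometry()

    # flow -------------------------------------------------------------------
    fl = raw.get("flow") or {}
    _check_keys(fl, {"mean_velocity", "waveform", "profile_mode"},
                "flow.", problems)
    mean_v = _parse_quantity(fl["mean_velocity"], "flow.mean_velocity",
                             problems) if "mean_velocity" in fl else 0.10
    profile_mode = fl.get("profile_mode", "mixed")
    if profile_mode not in ("mixed", "plug", "developed"):
        problems.append(f"flow.profile_mode: unknown mode {profile_mode!r}")
    waveform = None
    wf = fl.get("waveform") or {}
    _check_keys(wf, {"landmarks", "coefficients", "csv_path", "period"},
                "flow.waveform.", problems)
    period = float(wf.get("period", 1.0))
    if "coefficients" in wf:
        waveform = FlowWaveform(tuple(float(c) for c in wf["coefficients"]),
                                period=period)
    elif "csv_path" in wf:
        import pandas as pd
        tv = pd.read_csv(wf["csv_path"])
        coef = np.polynomial.polynomial.polyfit(
            tv.iloc[:, 0], tv.iloc[:, 1], 9)
        waveform = FlowWaveform(tuple(coef), period=period)
    elif "landmarks" in wf:
        lk = wf["landmarks"]
        _check_keys(lk, {f.name for f in dataclasses.fields(
            WaveformLandmarks)}, "flow.waveform.landmarks.", problems)
        try:
            waveform = make_waveform(mean=mean_v, period=period,
                                     landmarks=WaveformLandmarks(**lk))
        except (TypeError, ValueError) as exc:
            problems.append(f"flow.waveform.landmarks: {exc}")

    # particle ---------------------------------------------------------------
    pa = raw.get("particle") or {}
    _check_keys(pa, {"core_material", "core_radius", "shell_material",
                     "shell_thickness"}, "particle.", problems)
    core_name = pa.get("core_material", "Fe3O4")
    if core_name not in mats:
        problems.append(f"particle.core_material: unknown material "
                        f"{core_name!r}")
        core_name = "Fe3O4"
    r_core = _parse_quantity(pa.get("core_radius", 50e-9),
                             "particle.core_radius", problems)
    if np.isfinite(r_core) and r_core <= 0:
        problems.append(f"particle.core_radius: must be positive, "
                        f"got {r_core:g} m")
    shell_name = pa.get("shell_material")
    if shell_name is not None and shell_name not in mats:
        problems.append(f"particle.shell_material: unknown material "
                        f"{shell_name!r}")
        shell_name = None
    thick = _parse_quantity(pa.get("shell_thickness", 0.0),
                            "particle.shell_thickness", problems)
    if np.isfinite(thick) and thick < 0:
        problems.append("particle.shell_thickness: must be non-negative")
    particle = None
    if not problems:
        try:
            particle = ParticleSpec(
                core=mats[core_name], core_radius=r_core,
                shell=mats[shell_name] if shell_name else None,
                shell_thickness=thick if shell_name else 0.0)
        except ValueError as exc:
            problems.append(f"particle: {exc}")

    # sim --------------------------------------------------------------------
    sm = raw.get("sim") or {}
    _check_keys(sm, {"n_particles", "injection_times", "dt", "t_max",
                     "temperature", "seed", "integrator", "brownian",
                     "particle_viscosity"}, "sim.", problems)
    sim_kwargs: dict[str, Any] = {}
    if "n_particles" in sm:
        sim_kwargs["n_particles"] = int(sm["n_particles"])
    if "injection_times" in sm:
        sim_kwargs["injection_times"] = tuple(
            _parse_quantity(t, "sim.injection_times", problems)
            for t in sm["injection_times"])
    for key in ("dt", "t_max", "temperature"):
        if key in sm:
            sim_kwargs[key] = _parse_quantity(sm[key], f"sim.{key}", problems)
    if "seed" in sm:
        sim_kwargs["seed"] = int(sm["seed"])
    for key in ("integrator", "particle_viscosity"):
        if key in sm:
            sim_kwargs[key] = sm[key]
    if "brownian" in sm:
        sim_kwargs["brownian"] = bool(sm["brownian"])
    if sim_kwargs.get("integrator", "overdamped") not in ("overdamped",
                                                          "inertial"):
        problems.append(f"sim.integrator: unknown integrator "
                        f"{sim_kwargs['integrator']!r}")

    # magnet -----------------------------------------------------------------
    mg = raw.get("magnet") or {}
    _check_keys(mg, {"center", "size", "b_rem", "axis", "calibrate", "mu_r"},
                "magnet.", problems)
    mag_center = tuple(_parse_quantity(v, "magnet.center", problems)
                       for v in mg.get("center", (0.02, -0.02)))
    size = mg.get("size", (0.0036, 0.020))
    mag_size = tuple(_parse_quantity(v, "magnet.size", problems)
                     for v in size)
    b_rem = _parse_quantity(mg.get("b_rem", 2.0), "magnet.b_rem", problems)
    axis = tuple(float(v) for v in mg.get("axis", (0.0, 1.0)))
    magnet = None
    if not problems:
        try:
            magnet = MagnetSpec(b_rem=b_rem, center=mag_center,
                                width=mag_size[0], height=mag_size[1],
                                axis=axis, mu_r=float(mg.get("mu_r", 1.05)))
        except ValueError as exc:
            problems.append(f"magnet: {exc}")

    if problems:
        raise ConfigError(problems)

    cfg = SimulationConfig(
        geometry=geometry, magnet=magnet, waveform=waveform,
        particle=particle, mean_inlet_velocity=mean_v,
        profile_mode=profile_mode, **sim_kwargs)

    cal = mg.get("calibrate")
    if cal is None and not mg:
        cal = {}       # empty magnet section -> default calibrated field
    if cal is not None:
        _check_keys(cal, {"point", "B", "gradB"}, "magnet.calibrate.",
                    problems)
        pt = cal.get("point")
        if pt is None:
            pt = (float(np.mean(cfg.geometry.magnet_footprint)),
                  cfg.geometry.width / 2)
        else:
            pt = tuple(_parse_quantity(v, "magnet.calibrate.point", problems)
                       for v in pt)
        b_t = _parse_quantity(cal.get("B", 0.5), "magnet.calibrate.B",
                              problems)
        g_t = _parse_quantity(cal.get("gradB", 180.0),
                              "magnet.calibrate.gradB", problems)
        if problems:
            raise ConfigError(problems)
        cfg = replace(cfg, magnet=calibrate_to_target(cfg.magnet, pt,
                                                      b_t, g_t))
    return cfg


def dump_config(cfg: SimulationConfig) -> dict:
    """Normalized plain-dict form of a config (SI numbers, YAML/JSON safe)."""
    wf = cfg.resolved_waveform()
    return {
        "magnet": {
            "center": list(cfg.magnet.center),
            "size": [cfg.magnet.width, cfg.magnet.height],
            "b_rem": cfg.magnet.b_rem,
            "axis": list(cfg.magnet.axis),
            "mu_r": cfg.magnet.mu_r,
        },
        "channel": {
            "width": cfg.geometry.width,
            "length": cfg.geometry.length,
            "magnet_footprint": list(cfg.geometry.magnet_footprint),
            "blood_density": cfg.geometry.blood_density,
        },
        "flow": {
            "mean_velocity": cfg.mean_inlet_velocity,
            "profile_mode": cfg.profile_mode,
            "waveform": {"coefficients": list(wf.coefficients),
                         "period": wf.period},
        },
        "particle": {
            "core_material": cfg.particle.core.name,
            "core_radius": cfg.particle.core_radius,
            "shell_material": (cfg.particle.shell.name
                               if cfg.particle.shell else None),
            "shell_thickness": cfg.particle.shell_thickness,
        },
        "sim": {
            "n_particles": cfg.n_particles,
            "injection_times": list(cfg.injection_times),
            "dt": cfg.dt,
            "t_max": cfg.t_max,
            "temperature": cfg.temperature,
            "seed": cfg.seed,
            "integrator": cfg.integrator,
            "brownian": cfg.brownian,
            "particle_viscosity": cfg.particle_viscosity,
        },
    }


@dataclasses.dataclass
class RunManifest:
    """Everything needed to replay a run bit-exactly."""

    config: dict
    seed: int
    version: str = _VERSION
    timestamp: str = ""
    outputs: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def for_run(cls, cfg: SimulationConfig,
                outputs: dict | None = None) -> "RunManifest":
        return cls(config=dump_config(cfg), seed=cfg.seed,
                   timestamp=_dt.datetime.now().isoformat(timespec="seconds"),
                   outputs=outputs or {})

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
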