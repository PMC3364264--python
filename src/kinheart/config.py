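"""YAML-driven simulation configs: validation, resolution, execution.

A config fully describes one run — mesh source, fiber field, schedule,
engine parameters, outputs — so a run is reproducible from the file alone.
The resolved config (defaults filled in) is echoed next to the outputs and
its hash is stamped into the measurement CSV header.
"""
from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import yaml

from .activation import ContractionCurve, ContractionSchedule, build_phase_shift_field
from .engine import Simulation
from .fibers import AngleRule, load_fiber_field, rule_based_fibers
from .generators import (
    CylinderSpec, GeneratedMesh, SheetSpec,
    load_sidecar, make_idealized_lv, make_thick_cylinder, make_thick_sheet,
)
from .measurements import (
    MeasurementSeries, cavity_volume, ejection_fraction,
    slant_angle, vertical_length, wall_thickness,
)
from .mesh import build_local_regions, load_tet_mesh, write_frame

log = logging.getLogger("kinheart")

__all__ = ["ConfigError", "load_config", "resolve_config", "run_simulation"]


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending field."""


DEFAULTS = {
    "seed": 0,
    "mesh": {"generator": "cylinder", "spec": {}},
    "fibers": {"mode": "rule", "rule": {}, "axis": [0.0, 0.0, 1.0],
               "direction": [0.0, 0.0, 1.0], "label": "ventricular"},
    "weights": {"mode": "anisotropic", "eps": 0.05, "exponent": 1.0},
    "schedule": {
        "cycle_T": 1.1, "a_mc": 0.5,
        "curves": {"ventricular": [[0.0, 0.0], [0.25, 0.0], [0.5, 1.0],
                                   [0.75, 1.0], [1.0, 0.0]]},
        "phase": None,
    },
    "engine": {"h": 0.01, "stiffness_M": 10, "damping": 0.9,
               "volume_preservation": True, "pins": None, "gravity": None},
    "run": {"n_cycles": 1.0},
    "outputs": {"directory": "out", "frame_stride": 0,
                "measurements": "measurements.csv"},
}


#: nested mappings with user-defined keys, replaced wholesale on merge
_FREEFORM = {"mesh.spec", "fibers.rule", "schedule.curves", "schedule.phase"}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = dict(base)
    for key, val in (override or {}).items():
        if key not in base:
            raise ConfigError(f"unknown config field {path + key!r}")
        if (isinstance(base[key], dict) and isinstance(val, dict)
                and path + key not in _FREEFORM):
            out[key] = _merge(base[key], val, path + key + ".")
        else:
            out[key] = val
    return out


def _check(cond: bool, field: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"config field {field!r}: {msg}")


def resolve_config(raw: dict) -> dict:
    """Fill defaults and validate; raises ConfigError naming the field."""
    cfg = _merge(DEFAULTS, raw or {})
    eng = cfg["engine"]
    _check(isinstance(eng["h"], (int, float)) and eng["h"] > 0, "engine.h",
           "time step must be a positive number")
    _check(isinstance(eng["stiffness_M"], int) and eng["stiffness_M"] >= 1,
           "engine.stiffness_M", "must be an integer >= 1")
    _check(0.0 <= eng["damping"] <= 1.0, "engine.damping", "must be in [0, 1]")
    sch = cfg["schedule"]
    _check(isinstance(sch["a_mc"], (int, float)) and 0 <= sch["a_mc"] < 1,
           "schedule.a_mc", "maximum contraction rate must be in [0, 1)")
    _check(sch["cycle_T"] > 0, "schedule.cycle_T", "must be positive")
    _check(cfg["mesh"]["generator"] in ("cylinder", "sheet", "lv", "files"),
           "mesh.generator", "must be one of cylinder, sheet, lv, files")
    _check(cfg["fibers"]["mode"] in ("rule", "constant", "file"), "fibers.mode",
           "must be 'rule', 'constant' or 'file'")
    _check(cfg["weights"]["mode"] in ("anisotropic", "uniform"),
           "weights.mode", "must be 'anisotropic' or 'uniform'")
    _check(cfg["run"]["n_cycles"] > 0, "run.n_cycles", "must be positive")
    for lab, knots in sch["curves"].items():
        try:
            ContractionCurve(tuple(map(tuple, knots)))
        except ValueError as exc:
            raise ConfigError(f"config field 'schedule.curves.{lab}': {exc}")
    return cfg


def load_config(path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return resolve_config(raw)


def config_hash(cfg: dict) -> str:
    text = yaml.safe_dump(cfg, sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def _build_mesh(cfg: dict) -> GeneratedMesh:
    mc = cfg["mesh"]
    gen = mc["generator"]
    spec = mc.get("spec") or {}
    try:
        if gen == "cylinder":
            return make_thick_cylinder(CylinderSpec(**spec))
        if gen == "sheet":
            return make_thick_sheet(SheetSpec(**spec))
        if gen == "lv":
            return make_idealized_lv(**spec)
    except TypeError as exc:
        raise ConfigError(f"config field 'mesh.spec': {exc}") from None
    for key in ("node", "ele"):
        _check(key in mc, f"mesh.{key}", "required when mesh.generator is 'files'")
    mesh = load_tet_mesh(mc["node"], mc["ele"])
    labels, depth = ({}, None)
    if mc.get("sidecar"):
        labels, depth = load_sidecar(mc["sidecar"])
    return GeneratedMesh(mesh, labels, depth)


def _build_fibers(cfg: dict, gen: GeneratedMesh):
    fc = cfg["fibers"]
    if fc["mode"] == "file":
        _check("file" in fc, "fibers.file", "required when fibers.mode is 'file'")
        return load_fiber_field(fc["file"])
    if fc["mode"] == "constant":
        from .fibers import FiberField

        d = np.asarray(fc["direction"], float)
        _check(np.linalg.norm(d) > 0, "fibers.direction", "must be nonzero")
        d = d / np.linalg.norm(d)
        n = gen.mesh.n_vertices
        return FiberField(np.tile(d, (n, 1)),
                          np.full(n, fc["label"], dtype=object))
    _check(gen.depth is not None, "fibers.mode",
           "rule-based fibers need a mesh with a transmural depth field")
    try:
        rule = AngleRule(**fc["rule"])
    except TypeError as exc:
        raise ConfigError(f"config field 'fibers.rule': {exc}") from None
    return rule_based_fibers(gen.mesh, gen.depth, axis=fc["axis"], rule=rule,
                             label=fc["label"])


def _resolve_pins(pins, gen: GeneratedMesh):
    if pins is None:
        return None
    if isinstance(pins, str):
        _check(pins in gen.labels, "engine.pins",
               f"label {pins!r} not present; available: {sorted(gen.labels)}")
        return gen.labels[pins]
    return np.asarray(pins, np.int64)


def build_simulation(cfg: dict) -> tuple[GeneratedMesh, Simulation]:
    gen = _build_mesh(cfg)
    fibers = _build_fibers(cfg, gen)
    wc = cfg["weights"]
    regions = build_local_regions(gen.mesh, fibers, wc["mode"],
                                  eps=wc["eps"], exponent=wc["exponent"])
    sch = cfg["schedule"]
    curves = {lab: ContractionCurve(tuple(map(tuple, knots)))
              for lab, knots in sch["curves"].items()}
    delays = None
    if sch.get("phase"):
        delays = build_phase_shift_field(
            gen.mesh, sch["phase"]["sources"], sch["phase"]["speed"])
    schedule = ContractionSchedule(curves=curves, cycle_T=sch["cycle_T"],
                                   a_mc=sch["a_mc"], delays=delays)
    eng = cfg["engine"]
    gravity = None if eng["gravity"] is None else np.asarray(eng["gravity"], float)
    sim = Simulation(
        gen.mesh, regions, fibers, schedule,
        h=eng["h"], stiffness_M=eng["stiffness_M"], damping=eng["damping"],
        volume_preservation=eng["volume_preservation"],
        pins=_resolve_pins(eng["pins"], gen), gravity=gravity,
    )
    return gen, sim


def _measurement_recorder(gen: GeneratedMesh):
    labels = gen.labels
    mesh = gen.mesh
    if "inner" in labels and "outer" in labels:
        inner, outer = labels["inner"], labels["outer"]
    elif "endocardium" in labels and "epicardium" in labels:
        inner, outer = labels["endocardium"], labels["epicardium"]
    else:
        return None

    def record(sim: Simulation):
        pos = sim.state.positions
        try:
            s_ext = slant_angle(mesh, mesh.vertices, pos, outer)
        except Exception:
            s_ext = float("nan")
        return (sim.state.time,
                wall_thickness(mesh, pos, inner, outer),
                vertical_length(pos),
                cavity_volume(mesh, pos, inner),
                s_ext)

    return record


def run_simulation(config_path, out_dir=None) -> dict:
    """Run a config end to end; write frames, measurements and the
    resolved-config echo; return a per-cycle summary dict."""
    from . import __version__

    cfg = load_config(config_path)
    out = Path(out_dir or cfg["outputs"]["directory"])
    out.mkdir(parents=True, exist_ok=True)
    gen, sim = build_simulation(cfg)

    chash = config_hash(cfg)
    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)

    n_steps = int(round(cfg["run"]["n_cycles"] * sim.schedule.cycle_T / sim.h))
    stride = cfg["outputs"]["frame_stride"]
    recorder = _measurement_recorder(gen)
    records = []

    def on_frame(k):
        if recorder is not None:
            records.append(recorder(sim))
        if stride and k % stride == 0:
            write_frame(gen.mesh, sim.state.positions, out / f"frame_{k:05d}.vtk")

    on_frame(0)
    for k in range(1, n_steps + 1):
        sim.step()
        on_frame(k)

    summary = {"config_hash": chash, "frames": n_steps + 1,
               "t_end": sim.state.time}
    if records:
        series = MeasurementSeries.from_records(records)
        series.to_csv(out / cfg["outputs"]["measurements"],
                      header_comment=f"kinheart {__version__} config {chash}")
        summary.update(
            W_min=float(series.W.min()), W_max=float(series.W.max()),
            L_min=float(series.L.min()), L_max=float(series.L.max()),
            V_min=float(series.V.min()), V_max=float(series.V.max()),
            S_ext_max=float(series.S_ext.max()),
            lvef_percent=ejection_fraction(series),
        )
        log.info("per-cycle summary: %s", summary)
    return summary
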