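"""Canned benchmark experiments on the procedural solids.

These functions assemble the standard study setups — the thick-walled
cylinder systole, the fiber-orientation comparison, the pinned-sheet
anisotropy test, and the idealized-LV ejection-fraction sweep — so a
full reproduction is a single call.  The CLI `suite` subcommand and the
acceptance script are thin wrappers around them.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .activation import ContractionCurve, ContractionSchedule
from .engine import Simulation
from .fibers import AngleRule, FiberField, rule_based_fibers
from .generators import (
    CylinderSpec, GeneratedMesh, SheetSpec,
    make_idealized_lv, make_thick_cylinder, make_thick_sheet,
)
from .measurements import (
    MeasurementSeries, cavity_volume, ejection_fraction,
    slant_angle, vertical_length, wall_thickness,
)
from .mesh import build_local_regions

__all__ = [
    "build_cylinder_sim",
    "run_cylinder_cycle",
    "plateau_mask",
    "fig5_suite",
    "fiber_orientation_cases",
    "fiber_orientation_suite",
    "sheet_sag",
    "sheet_sag_suite",
    "build_lv_sim",
    "lv_ejection_fraction",
    "lvef_suite",
]

#: full-activation phase window of the trapezoid curve
PLATEAU = (0.5, 0.75)


@dataclass
class CylinderRun:
    gen: GeneratedMesh
    sim: Simulation
    series: MeasurementSeries


def _measure_cylinder(gen: GeneratedMesh):
    mesh = gen.mesh
    inner, outer = gen.labels["inner"], gen.labels["outer"]

    def record(sim: Simulation):
        pos = sim.state.positions
        return (
            sim.state.time,
            wall_thickness(mesh, pos, inner, outer),
            vertical_length(pos),
            cavity_volume(mesh, pos, inner),
            slant_angle(mesh, mesh.vertices, pos, outer),
        )

    return record


def build_cylinder_sim(
    a_mc: float = 0.5,
    rule: AngleRule | None = None,
    weight_mode: str = "anisotropic",
    spec: CylinderSpec | None = None,
    curve: ContractionCurve | None = None,
    cycle_T: float = 1.1,
    h: float = 0.01,
    stiffness_M: int = 10,
    damping: float = 0.9,
    volume_preservation: bool = True,
) -> tuple[GeneratedMesh, Simulation]:
    """Cylinder-LV setup: rule-based fibers (default transmural +60 to -60
    deg), trapezoid time-contraction curve, free boundaries."""
    gen = make_thick_cylinder(spec)
    fibers = rule_based_fibers(gen.mesh, gen.depth, rule=rule or AngleRule())
    regions = build_local_regions(gen.mesh, fibers, weight_mode)
    schedule = ContractionSchedule(
        curves={"ventricular": curve or ContractionCurve()},
        cycle_T=cycle_T, a_mc=a_mc,
    )
    sim = Simulation(
        gen.mesh, regions, fibers, schedule, h=h, stiffness_M=stiffness_M,
        damping=damping, volume_preservation=volume_preservation,
    )
    return gen, sim


def run_cylinder_cycle(a_mc: float = 0.5, n_cycles: float = 1.0,
                       **kwargs) -> CylinderRun:
    """Run whole cycles of the cylinder systole and record W, L, V, S_ext
    every frame (frame 0 is the rest state)."""
    gen, sim = build_cylinder_sim(a_mc=a_mc, **kwargs)
    n_steps = int(round(n_cycles * sim.schedule.cycle_T / sim.h))
    records = sim.run(n_steps, record=_measure_cylinder(gen))
    return CylinderRun(gen, sim, MeasurementSeries.from_records(records))


def plateau_mask(times: np.ndarray, cycle_T: float,
                 window: tuple = (0.6, 0.75)) -> np.ndarray:
    """Frames whose cycle phase falls in the (settled) full-activation
    window; the default skips the first 40% of the plateau so transient
    lag has died out."""
    phase = (np.asarray(times, float) % cycle_T) / cycle_T
    return (phase >= window[0]) & (phase <= window[1])


def fig5_suite(a_mcs=(0.1, 0.3, 0.5, 0.7), out_dir=None, **kwargs) -> pd.DataFrame:
    """Cylinder systole at several maximum contraction rates; per-run CSVs
    plus a summary of peak W, min L, min V, peak S_ext."""
    rows = []
    for a_mc in a_mcs:
        run = run_cylinder_cycle(a_mc=a_mc, **kwargs)
        s = run.series
        if out_dir is not None:
            s.to_csv(f"{out_dir}/cylinder_amc{a_mc:g}.csv",
                     header_comment=f"cylinder systole, a_mc={a_mc:g}")
        rows.append({
            "a_mc": a_mc,
            "W_rest": s.W[0], "W_peak": s.W.max(),
            "L_rest": s.L[0], "L_min": s.L.min(),
            "V_rest": s.V[0], "V_min": s.V.min(),
            "S_ext_peak": s.S_ext.max(),
        })
    return pd.DataFrame(rows)


#: the four fiber-orientation cases of the orientation study
ORIENTATION_CASES = {
    "helix_90": AngleRule(0.0, 90.0, 90.0),
    "helix_-60": AngleRule(0.0, -60.0, -60.0),
    "helix_0": AngleRule(0.0, 0.0, 0.0),
    "transmural_+60_-60": AngleRule(0.0, 60.0, -60.0),
}

#: per-case maximum contraction rates emulating the reference calibration
#: protocol (each case's rate was matched, on a 0.05 grid, to an
#: independent physics run of the same muscle model): the transmural and
#: 90 deg cases keep the benchmark-matched 0.5; the -60 deg helix matches
#: a non-pumping target, giving the smallest grid value; the 0 deg case
#: has only a qualitative target and is fixed at half the anchor.  See the
#: methods note for the full rationale.
ORIENTATION_TUNED_AMC = {
    "helix_90": 0.5,
    "helix_-60": 0.05,
    "helix_0": 0.25,
    "transmural_+60_-60": 0.5,
}


def fiber_orientation_cases(a_mc=None, **kwargs) -> dict[str, dict]:
    """Contract the cylinder to the full-activation plateau under each of
    the four helix-angle rules; report the cavity-volume decrease ratio and
    the vertical-length change.

    ``a_mc`` may be a single rate for all cases or a per-case mapping;
    default is the tuned per-case mapping ORIENTATION_TUNED_AMC.
    """
    rates = ORIENTATION_TUNED_AMC if a_mc is None else a_mc
    if not isinstance(rates, dict):
        rates = {name: float(a_mc) for name in ORIENTATION_CASES}
    out = {}
    for name, rule in ORIENTATION_CASES.items():
        a_mc_case = rates[name]
        gen, sim = build_cylinder_sim(a_mc=a_mc_case, rule=rule, **kwargs)
        mesh = gen.mesh
        inner = gen.labels["inner"]
        v0 = cavity_volume(mesh, mesh.vertices, inner)
        l0 = vertical_length(mesh.vertices)
        # run into the middle of the plateau and let the shape settle
        n_steps = int(round(0.7 * sim.schedule.cycle_T / sim.h))
        sim.run(n_steps)
        pos = sim.state.positions
        out[name] = {
            "dV_ratio": (v0 - cavity_volume(mesh, pos, inner)) / v0,
            "dL": vertical_length(pos) - l0,
            "a_mc": a_mc_case,
        }
    return out


def fiber_orientation_suite(a_mc=None, **kwargs) -> pd.DataFrame:
    cases = fiber_orientation_cases(a_mc=a_mc, **kwargs)
    return pd.DataFrame(
        [{"case": k, **v} for k, v in cases.items()]
    ).set_index("case")


# -- pinned-sheet anisotropy ----------------------------------------------

#: constant fiber directions for the hanging-plate test (plate in the x-z
#: plane, gravity along -z): along the hanging direction, across it, 45 deg
SHEET_FIBERS = {
    "vertical": (0.0, 0.0, 1.0),
    "slant_45": (np.sqrt(0.5), 0.0, np.sqrt(0.5)),
    "horizontal": (1.0, 0.0, 0.0),
}


def sheet_sag(
    fiber_direction,
    spec: SheetSpec | None = None,
    h: float = 0.005,
    stiffness_M: int = 3,
    gravity: float = 9800.0,
    n_steps: int = 600,
) -> float:
    """Steady sag of a vertical plate pinned along its top face under
    gravity, with a constant fiber field and anisotropic weights.

    Returns the mean displacement (mm) of the bottom-face vertices after
    settling: smaller sag = stiffer hanging behavior.
    """
    spec = spec or SheetSpec(x_len=100.0, y_len=20.0, z_len=100.0,
                             n_x=10, n_y=2, n_z=10)
    gen = make_thick_sheet(spec)
    f = np.asarray(fiber_direction, float)
    f = f / np.linalg.norm(f)
    fibers = FiberField(
        np.tile(f, (gen.mesh.n_vertices, 1)),
        np.full(gen.mesh.n_vertices, "ventricular", dtype=object),
    )
    regions = build_local_regions(gen.mesh, fibers, "anisotropic")
    schedule = ContractionSchedule(a_mc=0.0)  # passive: gravity only
    sim = Simulation(
        gen.mesh, regions, fibers, schedule, h=h, stiffness_M=stiffness_M,
        volume_preservation=False, pins=gen.labels["top"],
        gravity=np.array([0.0, 0.0, -gravity]),
    )
    sim.run(n_steps)
    bottom = gen.labels["bottom"]
    disp = sim.state.positions[bottom] - gen.mesh.vertices[bottom]
    return float(np.linalg.norm(disp, axis=1).mean())


def sheet_sag_suite(**kwargs) -> pd.DataFrame:
    rows = [{"fibers": name, "sag_mm": sheet_sag(direction, **kwargs)}
            for name, direction in SHEET_FIBERS.items()]
    return pd.DataFrame(rows).set_index("fibers")


# -- idealized-LV ejection fraction ---------------------------------------


def build_lv_sim(
    a_mc: float = 0.5,
    weight_mode: str = "anisotropic",
    rule: AngleRule | None = None,
    cycle_T: float = 1.1,
    h: float = 0.01,
    stiffness_M: int = 10,
    **lv_kwargs,
) -> tuple[GeneratedMesh, Simulation]:
    """Idealized-LV setup: transmural rule-based fibers, trapezoid curve,
    base ring pinned, global volume preservation on."""
    gen = make_idealized_lv(**lv_kwargs)
    fibers = rule_based_fibers(gen.mesh, gen.depth, rule=rule or AngleRule())
    regions = build_local_regions(gen.mesh, fibers, weight_mode)
    schedule = ContractionSchedule(
        curves={"ventricular": ContractionCurve()}, cycle_T=cycle_T, a_mc=a_mc,
    )
    sim = Simulation(
        gen.mesh, regions, fibers, schedule, h=h, stiffness_M=stiffness_M,
        pins=gen.labels["base"],
    )
    return gen, sim


def lv_ejection_fraction(a_mc: float = 0.5, weight_mode: str = "anisotropic",
                         **kwargs) -> float:
    """LVEF over one beat of the idealized LV."""
    gen, sim = build_lv_sim(a_mc=a_mc, weight_mode=weight_mode, **kwargs)
    mesh, endo = gen.mesh, gen.labels["endocardium"]

    def record(s: Simulation):
        return cavity_volume(mesh, s.state.positions, endo)

    n_steps = int(round(sim.schedule.cycle_T / sim.h))
    volumes = sim.run(n_steps, record=record)
    return ejection_fraction(np.asarray(volumes))


def lvef_suite(a_mcs=(0.4, 0.5, 0.6, 0.7), **kwargs) -> pd.DataFrame:
    """LVEF table over MC rates for anisotropic vs uniform region weights."""
    rows = []
    for a_mc in a_mcs:
        rows.append({
            "a_mc": a_mc,
            "lvef_anisotropic": lv_ejection_fraction(a_mc, "anisotropic", **kwargs),
            "lvef_uniform": lv_ejection_fraction(a_mc, "uniform", **kwargs),
        })
    return pd.DataFrame(rows).set_index("a_mc")
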