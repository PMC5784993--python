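"""Registry of the canonical simulation experiments.

Each entry reproduces one of the study designs: stiffness sweeps
(modulus x area), load sweeps (mass x area), catch sweeps (delay x modulus,
mass x delay), single-run trace comparisons across tendon compliances, the
100 ms catch compliant-vs-rigid contrast, and the modulus response curves
under combinations of catch delay and stretched starts. Grid sizes default
to the full 100 increments per axis; pass a smaller ``n`` for quick looks.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .muscle import MuscleSpec
from .simulate import SimConfig, SimResult, SimTrace, run_simulation
from .sweep import Axis, SweepSpec, SweepSurface, pearson, run_sweep, surface_argmax
from .tendon_load import LoadSpec, TendonSpec

__all__ = [
    "load_mass_for_fraction",
    "fig1_spec", "fig2_spec", "fig3_spec", "fig4_spec",
    "run_fig6", "run_fig7", "run_fig8",
    "summarize_stiffness_sweep", "summarize_load_sweep",
    "summarize_catch_sweep", "summarize_catch_contrast",
    "EXPERIMENTS",
]

GPA = 1e9
CM2 = 1e-4  # m2

_MODULUS_RANGE = (0.001 * GPA, 5.0 * GPA)
_AREA_RANGE = (0.001 * CM2, 1.0 * CM2)
_SWEEP_SIM = SimConfig(record_trace=False, max_time=2.0)


def load_mass_for_fraction(fraction: float,
                           muscle: Optional[MuscleSpec] = None,
                           gravity: float = 9.81) -> float:
    """Load mass (kg) whose weight is ``fraction`` of maximal isometric
    force (e.g. 0.20 -> the default 485 g load)."""
    muscle = muscle or MuscleSpec()
    return fraction * muscle.p0_force / gravity


def fig1_spec(n: int = 100, muscle: Optional[MuscleSpec] = None) -> SweepSpec:
    """Tendon modulus x area sweep at the 20%-P0 load, no catch."""
    muscle = muscle or MuscleSpec()
    return SweepSpec(
        axis1=Axis("tendon_modulus", *_MODULUS_RANGE, n=n),
        axis2=Axis("tendon_area", *_AREA_RANGE, n=n),
        muscle=muscle,
        load=LoadSpec(mass=load_mass_for_fraction(0.20, muscle)),
        sim=_SWEEP_SIM,
    )


def fig2_spec(n: int = 100, muscle: Optional[MuscleSpec] = None) -> SweepSpec:
    """Load mass (0.001%-100% of P0) x tendon area at E = 0.01 GPa."""
    muscle = muscle or MuscleSpec()
    return SweepSpec(
        axis1=Axis("load_mass", load_mass_for_fraction(1e-5, muscle),
                   load_mass_for_fraction(1.0, muscle), n=n),
        axis2=Axis("tendon_area", *_AREA_RANGE, n=n),
        muscle=muscle,
        tendon=TendonSpec(youngs_modulus=0.01 * GPA),
        load=LoadSpec(mass=1.0),  # overridden per cell
        sim=_SWEEP_SIM,
    )


def fig3_spec(n: int = 100, muscle: Optional[MuscleSpec] = None) -> SweepSpec:
    """Catch delay (0-500 ms) x tendon modulus at the 20%-P0 load."""
    muscle = muscle or MuscleSpec()
    return SweepSpec(
        axis1=Axis("catch_delay", 0.0, 0.5, n=n),
        axis2=Axis("tendon_modulus", *_MODULUS_RANGE, n=n),
        muscle=muscle,
        load=LoadSpec(mass=load_mass_for_fraction(0.20, muscle)),
        sim=_SWEEP_SIM,
    )


def fig4_spec(n: int = 100, rigid: bool = False,
              muscle: Optional[MuscleSpec] = None) -> SweepSpec:
    """Load mass x catch delay with a compliant (0.01 GPa) or functionally
    rigid (5 GPa) tendon."""
    muscle = muscle or MuscleSpec()
    return SweepSpec(
        axis1=Axis("load_mass", load_mass_for_fraction(1e-5, muscle),
                   load_mass_for_fraction(1.0, muscle), n=n),
        axis2=Axis("catch_delay", 0.0, 0.5, n=n),
        muscle=muscle,
        tendon=TendonSpec(youngs_modulus=(5.0 if rigid else 0.01) * GPA),
        load=LoadSpec(mass=1.0),
        sim=_SWEEP_SIM,
    )


def _single(modulus_gpa: float, mass: float, catch_delay: float = 0.0,
            initial_pct: float = 100.0,
            muscle: Optional[MuscleSpec] = None,
            dt: float = 1e-4) -> tuple[SimTrace, SimResult]:
    muscle = muscle or MuscleSpec()
    cfg = SimConfig(dt=dt, initial_muscle_length_pct=initial_pct)
    return run_simulation(muscle, TendonSpec(youngs_modulus=modulus_gpa * GPA),
                          LoadSpec(mass=mass, catch_delay=catch_delay), cfg)


def run_fig6(muscle: Optional[MuscleSpec] = None) -> dict:
    """Trace comparison across compliances at the 20%-P0 load, no catch:
    excessively compliant (A), ideally compliant (B), rigid (C)."""
    muscle = muscle or MuscleSpec()
    mass = load_mass_for_fraction(0.20, muscle)
    return {label: _single(e_gpa, mass, muscle=muscle)
            for label, e_gpa in
            [("A", 0.00968), ("B", 0.0159), ("C", 0.538)]}


def run_fig7(muscle: Optional[MuscleSpec] = None) -> dict:
    """100 ms catch, 100 g load: compliant (0.0159 GPa) vs functionally
    rigid (5 GPa) tendon."""
    muscle = muscle or MuscleSpec()
    return {label: _single(e_gpa, 0.100, catch_delay=0.100, muscle=muscle)
            for label, e_gpa in [("compliant", 0.0159), ("rigid", 5.0)]}


def run_fig8(n: int = 100, muscle: Optional[MuscleSpec] = None) -> pd.DataFrame:
    """Lift height vs tendon modulus under four conditions: plain (T),
    500 ms catch (TD), 120% L0 start (TS), both (TDS)."""
    muscle = muscle or MuscleSpec()
    mass = load_mass_for_fraction(0.20, muscle)
    moduli = np.geomspace(*_MODULUS_RANGE, n)
    conditions = {"T": (0.0, 100.0), "TD": (0.5, 100.0),
                  "TS": (0.0, 120.0), "TDS": (0.5, 120.0)}
    rows = []
    for label, (delay, pct) in conditions.items():
        for e_pa in moduli:
            cfg = SimConfig(record_trace=False, initial_muscle_length_pct=pct,
                            max_time=2.0)
            _, res = run_simulation(
                muscle, TendonSpec(youngs_modulus=e_pa),
                LoadSpec(mass=mass, catch_delay=delay), cfg)
            rows.append({"condition": label, "modulus_Pa": e_pa,
                         "lift_height_m": res.apex_height,
                         "peak_mtc_power_W": res.peak_mtc_power})
    return pd.DataFrame(rows)


def summarize_stiffness_sweep(surface: SweepSurface) -> dict:
    """Summary of a modulus x area sweep: argmax, the iso-stiffness ridge
    it lies on, and improvements over the most-rigid corner cell."""
    e_opt, a_opt, h_opt = surface_argmax(surface, "lift_height")
    h_rigid = float(surface.lift_height[-1, -1])  # stiffest corner
    p_rigid = float(surface.peak_mtc_power[-1, -1])
    p_max = float(np.nanmax(surface.peak_mtc_power))
    tendon_length = surface.spec.tendon.rest_length
    return {
        "argmax_modulus_gpa": e_opt / GPA,
        "argmax_area_cm2": a_opt / CM2,
        "argmax_modulus_area_gpa_cm2": e_opt * a_opt / GPA / CM2,
        "argmax_modulus_over_length_gpa_per_m": e_opt / GPA / tendon_length,
        "max_lift_height_cm": h_opt * 100.0,
        "rigid_lift_height_cm": h_rigid * 100.0,
        "lift_gain_pct": 100.0 * (h_opt - h_rigid) / h_rigid,
        "max_peak_mtc_power_W": p_max,
        "rigid_peak_mtc_power_W": p_rigid,
        "power_gain_pct": 100.0 * (p_max - p_rigid) / p_rigid,
        "height_power_pearson_r": pearson(surface.lift_height,
                                          surface.peak_mtc_power),
    }


def summarize_load_sweep(surface: SweepSurface) -> dict:
    """Summary of a load-mass x area sweep: best lift, its mass, and the
    rigid-tendon lift at the same mass (largest-area cell of that row)."""
    m_opt, a_opt, h_opt = surface_argmax(surface, "lift_height")
    i = int(np.argmin(np.abs(surface.axis1_values - m_opt)))
    h_rigid_same_mass = float(surface.lift_height[i, -1])
    return {
        "max_lift_height_cm": h_opt * 100.0,
        "argmax_load_mass_g": m_opt * 1000.0,
        "argmax_area_cm2": a_opt / CM2,
        "rigid_lift_same_mass_cm": h_rigid_same_mass * 100.0,
        "lift_gain_pct": 100.0 * (h_opt - h_rigid_same_mass)
                         / h_rigid_same_mass,
        "height_power_pearson_r": pearson(surface.lift_height,
                                          surface.peak_mtc_power),
    }


def summarize_catch_sweep(surface: SweepSurface) -> dict:
    """Summary of a sweep with a catch-delay axis."""
    x1, x2, h_opt = surface_argmax(surface, "lift_height")
    return {
        "argmax_axis1": x1,
        "argmax_axis2": x2,
        "max_lift_height_cm": h_opt * 100.0,
        "height_power_pearson_r": pearson(surface.lift_height,
                                          surface.peak_mtc_power),
    }


def summarize_catch_contrast(runs: dict,
                             muscle: Optional[MuscleSpec] = None) -> dict:
    """Work/velocity decomposition of the compliant-vs-rigid catch runs."""
    muscle = muscle or MuscleSpec()
    out = {}
    for label, (_, res) in runs.items():
        out[label] = {
            "total_muscle_work_J": res.total_muscle_work,
            "work_before_release_J": res.work_before_release,
            "work_after_release_J": res.work_after_release,
            "lift_height_cm": res.apex_height * 100.0,
            "peak_load_velocity_cm_s": res.peak_load_velocity * 100.0,
            "peak_load_velocity_pct_vmax": res.peak_load_velocity_pct_vmax,
            "peak_mtc_power_W": res.peak_mtc_power,
        }
    out["work_ratio_compliant_over_rigid"] = (
        runs["compliant"][1].total_muscle_work
        / runs["rigid"][1].total_muscle_work)
    out["lift_ratio_compliant_over_rigid"] = (
        runs["compliant"][1].apex_height / runs["rigid"][1].apex_height)
    return out


def _run_registry_sweep(builder: Callable[..., SweepSpec], summarize):
    def runner(n: int = 100, **kw):
        surface = run_sweep(builder(n=n, **kw))
        return surface, summarize(surface)
    return runner


#: experiment name -> callable(n=...) returning (surface, summary) for
#: sweeps, or the run dict / DataFrame for trace experiments
EXPERIMENTS = {
    "fig1": _run_registry_sweep(fig1_spec, summarize_stiffness_sweep),
    "fig2": _run_registry_sweep(fig2_spec, summarize_load_sweep),
    "fig3": _run_registry_sweep(fig3_spec, summarize_catch_sweep),
    "fig4a": _run_registry_sweep(fig4_spec, summarize_catch_sweep),
    "fig4c": _run_registry_sweep(
        lambda n=100, **kw: fig4_spec(n=n, rigid=True, **kw),
        summarize_catch_sweep),
    "fig6": lambda n=100, **kw: run_fig6(**kw),
    "fig7": lambda n=100, **kw: run_fig7(**kw),
    "fig8": lambda n=100, **kw: run_fig8(n=n, **kw),
}
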