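"""Forward simulation of the coupled muscle-tendon-load system.

A run starts from rest (activation zero, load on the ground, tendon
pre-strained against any passive muscle force), advances in fixed 100 us
steps through the caught -> grounded -> airborne phases, and ends when the
muscle can no longer generate force (shortening limit or zero force), after
which ballistic extrapolation gives the apex height the load will reach.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import _kernel as K
from .muscle import MuscleSpec, passive_fl_scale
from .tendon_load import LoadSpec, TendonSpec

__all__ = [
    "SimConfig",
    "SimState",
    "SimTrace",
    "SimResult",
    "ballistic_apex",
    "initial_equilibrium",
    "solve_step",
    "run_simulation",
]

PHASE_NAMES = {K.CAUGHT: "caught", K.GROUNDED: "grounded", K.AIRBORNE: "airborne"}
PHASE_CODES = {v: k for k, v in PHASE_NAMES.items()}
TERMINATION_NAMES = {
    K.TERM_ACTIVE_EXHAUSTED: "active_force_exhausted",
    K.TERM_FORCE_ZERO: "force_zero",
    K.TERM_MAX_TIME: "max_time",
    K.TERM_STALLED: "stalled",
}

#: columns of the trace DataFrame (kernel column order)
TRACE_COLUMNS = [
    "t_s", "force_N", "muscle_len_m", "tendon_elong_m", "load_h_m",
    "load_v_mps", "act", "fl", "fv", "vm_mps", "p_muscle_W", "p_mtc_W",
    "work_muscle_J", "e_stored_J", "work_load_J", "phase",
]
#: columns written to trace CSV files
TRACE_CSV_COLUMNS = [
    "t_s", "force_N", "muscle_len_m", "tendon_elong_m", "load_h_m",
    "load_v_mps", "act", "fl", "fv", "p_muscle_W", "p_mtc_W",
    "work_muscle_J", "e_stored_J",
]


@dataclass(frozen=True)
class SimConfig:
    """Solver settings: step size, safety cap, start length, residual
    tolerance (N) of the per-step force balance."""

    dt: float = 1e-4
    max_time: float = 5.0
    initial_muscle_length_pct: float = 100.0
    solver_tolerance: float = 1e-9
    record_trace: bool = True

    def __post_init__(self):
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if not 50.0 <= self.initial_muscle_length_pct <= 150.0:
            raise ValueError("initial muscle length must be within 50-150 %L0")
        if not self.max_time > 0:
            raise ValueError("max_time must be > 0")


@dataclass
class SimState:
    """Instantaneous system state. ``load_height`` is measured from the
    load's resting position; ``load_velocity`` is upward-positive."""

    t: float
    muscle_length: float
    tendon_elongation: float
    load_height: float
    load_velocity: float
    force: float
    phase: str = "grounded"


class SimTrace:
    """Per-step history of a run (thin wrapper over a DataFrame)."""

    def __init__(self, df: pd.DataFrame, rest_length: float):
        self.df = df
        self._rest_length = rest_length

    def __len__(self):
        return len(self.df)

    def __getitem__(self, col):
        return self.df[col].to_numpy()

    def to_csv(self, path) -> None:
        self.df[TRACE_CSV_COLUMNS].to_csv(path, index=False)

    @property
    def vm_lengths_per_s(self) -> np.ndarray:
        """Muscle shortening velocity normalized to optimal length."""
        return self.df["vm_mps"].to_numpy() / self._rest_length


@dataclass
class SimResult:
    """Scalar outcomes of a run."""

    apex_height: float
    peak_mtc_power: float
    peak_muscle_power: float
    total_muscle_work: float
    work_before_release: float
    work_after_release: float
    peak_load_velocity: float
    peak_load_velocity_pct_vmax: float
    termination_reason: str

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def ballistic_apex(height: float, velocity: float, g: float = 9.81) -> float:
    """Maximal height a free load reaches: ``h + max(v, 0)^2 / (2 g)``."""
    if height < 0:
        raise ValueError("height must be >= 0")
    v = max(velocity, 0.0)
    return height + v * v / (2.0 * g)


def initial_equilibrium(muscle: MuscleSpec, tendon: TendonSpec,
                        initial_pct: float) -> tuple[float, float]:
    """Static pre-strain before activation begins.

    With the load supported by the ground/catch, any passive muscle force at
    the set initial length stretches the tendon, shortening the muscle until
    ``k e0`` balances the passive force at the shortened length. Returns
    ``(muscle_length_m, tendon_elongation_m)``.
    """
    L0 = muscle.rest_length
    lm_nom = initial_pct / 100.0 * L0
    k = tendon.stiffness
    p0 = muscle.p0_force

    def resid(e0):
        pct = 100.0 * (lm_nom - e0) / L0
        return k * e0 - p0 * passive_fl_scale(pct, muscle.passive_fl_coeffs)

    if resid(0.0) >= 0.0:  # no passive force at the set length
        return lm_nom, 0.0
    lo, hi = 0.0, lm_nom  # resid(lm_nom) > 0: passive vanishes well before
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if resid(mid) < 0.0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-16:
            break
    e0 = 0.5 * (lo + hi)
    return lm_nom - e0, e0


def _kernel_args(muscle: MuscleSpec, tendon: TendonSpec, load: LoadSpec):
    afl = np.asarray(muscle.active_fl_coeffs, dtype=float)
    pfl = np.asarray(muscle.passive_fl_coeffs, dtype=float)
    return dict(
        k=tendon.stiffness, m=load.mass, g=load.gravity,
        catch_delay=load.catch_delay, p0f=muscle.p0_force,
        L0=muscle.rest_length, afl=afl, pfl=pfl,
        a_rel=muscle.hill_a_rel, b=muscle.hill_b,
        act_t=muscle.activation.times, act_a=muscle.activation.scales,
        afl_peak=muscle.active_fl_peak,
    )


def solve_step(state: SimState, muscle: MuscleSpec, tendon: TendonSpec,
               load: LoadSpec, cfg: SimConfig,
               allow_zero_force: bool = False) -> SimState:
    """Advance one step: the same simultaneous force-balance solve the full
    run uses, exposed for single-step inspection.

    Raises ``RuntimeError`` if the bracketed solve cannot converge; a solved
    force of zero (slack / exhausted muscle) returns phase ``terminated``
    unless ``allow_zero_force`` permits an idle step (muscle not yet
    activated).
    """
    if state.phase == "terminated":
        raise ValueError("cannot advance a terminated state")
    ka = _kernel_args(muscle, tendon, load)
    status, phase, e2, y2, v2, lm2, vm, act, fla_raw, fv = K.advance(
        state.t, cfg.dt, PHASE_CODES[state.phase], state.tendon_elongation,
        state.load_height, state.load_velocity, state.muscle_length,
        ka["k"], ka["m"], ka["g"], ka["catch_delay"], ka["p0f"], ka["L0"],
        ka["afl"], ka["pfl"], ka["a_rel"], ka["b"], ka["act_t"], ka["act_a"],
        ka["afl_peak"], cfg.solver_tolerance, allow_zero_force)
    if status == K.TERM_NO_CONVERGENCE:
        raise RuntimeError(
            f"per-step force balance did not converge at t={state.t:.6f}s "
            f"(e={state.tendon_elongation:.3e}, F={state.force:.3e})")
    if status == K.TERM_FORCE_ZERO:
        return SimState(state.t, state.muscle_length, state.tendon_elongation,
                        state.load_height, state.load_velocity, 0.0,
                        phase="terminated")
    return SimState(state.t + cfg.dt, lm2, e2, y2, v2, ka["k"] * e2,
                    phase=PHASE_NAMES[phase])


def run_simulation(muscle: MuscleSpec, tendon: TendonSpec, load: LoadSpec,
                   cfg: Optional[SimConfig] = None
                   ) -> tuple[Optional[SimTrace], SimResult]:
    """Simulate a full contraction and return ``(trace, result)``.

    ``trace`` is ``None`` when ``cfg.record_trace`` is false (sweeps).
    """
    cfg = cfg or SimConfig()
    lm0, e0 = initial_equilibrium(muscle, tendon, cfg.initial_muscle_length_pct)
    ka = _kernel_args(muscle, tendon, load)
    (tr, n, term, apex, peak_pmtc, peak_pmusc, w_musc, w_before, peak_v,
     t_end, phase, e, y, v, lm, force, e_stored, w_load) = K.simulate(
        ka["k"], ka["m"], ka["g"], ka["catch_delay"], ka["p0f"], ka["L0"],
        ka["afl"], ka["pfl"], ka["a_rel"], ka["b"], ka["act_t"], ka["act_a"],
        ka["afl_peak"], cfg.dt, cfg.max_time, lm0, e0,
        cfg.solver_tolerance, cfg.record_trace)
    if term == K.TERM_NO_CONVERGENCE:
        raise RuntimeError(
            f"simulation failed to converge at t={t_end:.6f}s "
            f"(k={ka['k']:.4g} N/m, m={ka['m']:.4g} kg)")

    vmax_mps = muscle.reporting_vmax * muscle.rest_length
    result = SimResult(
        apex_height=float(apex),
        peak_mtc_power=float(peak_pmtc),
        peak_muscle_power=float(peak_pmusc),
        total_muscle_work=float(w_musc),
        work_before_release=float(w_before),
        work_after_release=float(w_musc - w_before),
        peak_load_velocity=float(peak_v),
        peak_load_velocity_pct_vmax=float(100.0 * peak_v / vmax_mps),
        termination_reason=TERMINATION_NAMES[term],
    )
    trace = None
    if cfg.record_trace:
        df = pd.DataFrame(np.asarray(tr), columns=TRACE_COLUMNS)
        trace = SimTrace(df, muscle.rest_length)
    return trace, result
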