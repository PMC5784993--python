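"""Synthetic muscle-characterization data with known ground truth.

The in vitro frog sartorius records behind the model (force--length points,
force--velocity points, 5 kHz tetanic force-rise traces) are not deposited
anywhere, so this module generates statistically similar stand-ins around
known parameter values: noisy samples of the force--length cubics, noisy
normalized Hill force--velocity points, and monotone-saturating tetanic
rises. It also provides the calibrated default activation curve used by
simulations.

The default activation time course is ``a(t) = (1 - exp(-t/tau))^p`` with
``tau = 42 ms`` and ``p = 2`` -- the simplest monotone saturating family that
satisfies the two calibration constraints the simulated system is known to
obey: the curve crosses the 20%-of-P0 load-support level near 25 ms (catch
delays shorter than that are null) and is essentially saturated by 200 ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitting import ForceLengthRecord, ForceVelocityRecord, TetanusRecord
from .muscle import (ACTIVE_FL_COEFFS, PASSIVE_FL_COEFFS, ActivationCurve,
                     MuscleSpec, active_fl_scale, fv_scale)

__all__ = [
    "SyntheticTruth",
    "default_activation_curve",
    "activation_truth",
    "gen_force_length",
    "gen_force_velocity",
    "gen_tetanus",
    "truth_muscle_spec",
]


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameters the generators sample around."""

    active_fl_coeffs: tuple = ACTIVE_FL_COEFFS
    passive_fl_coeffs: tuple = PASSIVE_FL_COEFFS
    hill_a_rel: float = 0.52
    hill_b: float = 4.17
    tau: float = 0.042  # s, activation rise time constant
    power: float = 2.0  # activation saturation exponent
    sigma_fl: float = 0.05  # force-length noise (fraction of max force)
    sigma_fv: float = 0.03  # force-velocity noise
    sigma_tetanus: float = 0.02  # tetanus noise

    def __post_init__(self):
        if not self.tau > 0:
            raise ValueError("tau must be > 0")
        if self.power < 1:
            raise ValueError("power must be >= 1")
        for s in (self.sigma_fl, self.sigma_fv, self.sigma_tetanus):
            if s < 0:
                raise ValueError("noise sigma must be >= 0")


def activation_truth(t, tau: float = 0.042, p: float = 2.0):
    """Saturating activation time course ``(1 - exp(-t/tau))^p``."""
    return (1.0 - np.exp(-np.asarray(t, dtype=float) / tau)) ** p


def default_activation_curve(tau: float = 0.042, p: float = 2.0,
                             resolution: float = 5000.0,
                             duration: float = 0.5) -> ActivationCurve:
    """Calibrated default force--time curve, sampled at ``resolution`` Hz.

    With the defaults ``a(25 ms) ~ 0.20`` and ``a(200 ms) ~ 0.98``; the last
    sample is pinned to exactly 1 so the curve saturates.
    """
    if not tau > 0 or p < 1:
        raise ValueError("require tau > 0 and p >= 1")
    t = np.arange(0.0, duration + 0.5 / resolution, 1.0 / resolution)
    a = activation_truth(t, tau, p)
    a[-1] = 1.0
    return ActivationCurve(t, a)


def gen_force_length(truth: SyntheticTruth, n: int = 60,
                     seed: int = 0) -> ForceLengthRecord:
    """Noisy active/passive force--length samples spanning 60-130 %L0.

    Passive values are the raw (unclamped) cubic plus noise -- the zero
    constraint below L0 applies at simulation time, not to the data.
    """
    if n < 5:
        raise ValueError("need at least 5 length samples")
    rng = np.random.default_rng(seed)
    pct = np.linspace(60.0, 130.0, n)
    active = active_fl_scale(pct, truth.active_fl_coeffs)
    passive = active_fl_scale(pct, truth.passive_fl_coeffs)  # raw cubic
    active = active + rng.normal(0.0, truth.sigma_fl, n)
    passive = passive + rng.normal(0.0, truth.sigma_fl, n)
    return ForceLengthRecord(pct_l0=pct, active=active, passive=passive)


def gen_force_velocity(truth: SyntheticTruth, n: int = 40,
                       seed: int = 0) -> ForceVelocityRecord:
    """Noisy normalized force--velocity samples on [0, 0.9 * V_zero]."""
    if n < 4:
        raise ValueError("need at least 4 force-velocity samples")
    rng = np.random.default_rng(seed)
    v_zero = truth.hill_b / truth.hill_a_rel
    v = np.linspace(0.0, 0.9 * v_zero, n)
    f = fv_scale(v, truth.hill_a_rel, truth.hill_b)
    f = np.clip(f + rng.normal(0.0, truth.sigma_fv, n), 0.0, 1.0)
    return ForceVelocityRecord(velocity=v, force=f)


def gen_tetanus(truth: SyntheticTruth, n_records: int = 5, seed: int = 0,
                duration: float = 0.5,
                resolution: float = 5000.0) -> list[TetanusRecord]:
    """Noisy tetanic force-rise records at 5 kHz from stimulation onset."""
    if n_records < 1:
        raise ValueError("need at least one tetanus record")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration + 0.5 / resolution, 1.0 / resolution)
    base = activation_truth(t, truth.tau, truth.power)
    out = []
    for _ in range(n_records):
        f = base + rng.normal(0.0, truth.sigma_tetanus, t.size)
        out.append(TetanusRecord(force=np.maximum(f, 0.0),
                                 resolution=resolution))
    return out


def truth_muscle_spec(truth: SyntheticTruth, **overrides) -> MuscleSpec:
    """MuscleSpec built directly from the ground-truth parameters."""
    kw = dict(
        hill_a_rel=truth.hill_a_rel,
        hill_b=truth.hill_b,
        active_fl_coeffs=truth.active_fl_coeffs,
        passive_fl_coeffs=truth.passive_fl_coeffs,
        activation=default_activation_curve(truth.tau, truth.power),
    )
    kw.update(overrides)
    return MuscleSpec(**kw)
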