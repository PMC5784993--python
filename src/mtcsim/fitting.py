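"""Muscle-characterization fits: force-length cubics, the normalized Hill
force-velocity relation, and the activation array built from tetanic records.

These are the procedures that turn pooled, normalized contractile records
into the scaling relations the simulator consumes: ordinary least-squares
cubic regressions over %L0, a nonlinear least-squares fit of the normalized
Hill hyperbola, and per-record normalization + averaging of tetanic force
rises into a single monotone activation array.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .muscle import ActivationCurve, MuscleSpec

__all__ = [
    "ForceLengthRecord",
    "ForceVelocityRecord",
    "TetanusRecord",
    "PolynomialFit",
    "HillFit",
    "fit_force_length",
    "fit_hill",
    "build_activation_curve",
    "muscle_spec_from_fits",
]


@dataclass
class ForceLengthRecord:
    """Pooled force-length samples: percent of L0, active and passive force
    normalized to the maximal active force."""

    pct_l0: np.ndarray
    active: np.ndarray
    passive: np.ndarray

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"pct_l0": self.pct_l0, "active": self.active,
                      "passive": self.passive}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ForceLengthRecord":
        df = pd.read_csv(path)
        return cls(df["pct_l0"].to_numpy(), df["active"].to_numpy(),
                   df["passive"].to_numpy())


@dataclass
class ForceVelocityRecord:
    """Pooled developed-force vs shortening-velocity samples (normalized to
    P0 and lengths/s)."""

    velocity: np.ndarray
    force: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.velocity, float)
        f = np.asarray(self.force, float)
        if np.any(v < 0):
            raise ValueError("shortening velocities must be >= 0")
        if np.any((f < 0) | (f > 1)):
            raise ValueError("normalized forces must lie in [0, 1]")
        self.velocity, self.force = v, f

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"velocity_Ls": self.velocity,
                      "force_rel": self.force}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ForceVelocityRecord":
        df = pd.read_csv(path)
        return cls(df["velocity_Ls"].to_numpy(), df["force_rel"].to_numpy())


@dataclass
class TetanusRecord:
    """Uniformly sampled tetanic force rise from stimulation onset."""

    force: np.ndarray
    resolution: float = 5000.0  # Hz

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.force.size) / self.resolution

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_s": self.times,
                      "force": self.force}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TetanusRecord":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy()
        res = 1.0 / float(np.mean(np.diff(t)))
        return cls(df["force"].to_numpy(), resolution=res)


@dataclass
class PolynomialFit:
    coeffs: tuple  # ascending powers, c0..c3
    r2: float

    def __call__(self, x):
        return np.polynomial.polynomial.polyval(np.asarray(x, float),
                                                np.asarray(self.coeffs))


@dataclass
class HillFit:
    a_rel: float
    b: float

    @property
    def v_zero(self) -> float:
        """Implied zero-force (unloaded) shortening velocity b / a_rel."""
        return self.b / self.a_rel

    def __call__(self, v):
        raw = self.b * (1.0 + self.a_rel) / (np.asarray(v, float) + self.b) \
            - self.a_rel
        return raw


def _r2(y, yhat) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_force_length(pct_l0, force, order: int = 3) -> PolynomialFit:
    """OLS polynomial regression of normalized force on percent of L0.

    Fits the *raw* samples (passive values are not clamped to zero below L0
    here -- that constraint belongs to the simulation, not the regression).
    """
    x = np.asarray(pct_l0, float)
    y = np.asarray(force, float)
    if np.unique(x).size < max(5, order + 1):
        raise ValueError("need at least 5 distinct lengths to fit a cubic")
    vand = np.vander(x, order + 1, increasing=True)
    if np.linalg.matrix_rank(vand) < order + 1:
        raise np.linalg.LinAlgError("rank-deficient design matrix")
    coeffs, *_ = np.linalg.lstsq(vand, y, rcond=None)
    return PolynomialFit(coeffs=tuple(coeffs), r2=_r2(y, vand @ coeffs))


_HILL_STARTS = [(0.5, 4.0), (0.1, 1.0), (0.25, 3.0), (1.0, 6.0), (2.0, 8.0)]


def fit_hill(velocity, force) -> HillFit:
    """Nonlinear least squares of the normalized Hill relation.

    Fits ``P = b (1 + a)/(V + b) - a`` (the hyperbola
    ``(P + a)(V + b) = b (1 + a)`` solved for force) to pooled normalized
    force-velocity samples. Restarts from a small grid of initial guesses;
    raises ``RuntimeError`` with the attempted starts if none converge.
    """
    v = np.asarray(velocity, float)
    f = np.asarray(force, float)
    if v.size < 4:
        raise ValueError("need at least 4 force-velocity samples")
    if f.min() > 0.5 or f.max() < 0.5:
        warnings.warn("force-velocity samples do not span low and high "
                      "force; Hill fit may be poorly constrained")

    def resid(theta):
        a, b = theta
        return b * (1.0 + a) / (v + b) - a - f

    best = None
    for start in _HILL_STARTS:
        sol = least_squares(resid, start, bounds=([1e-6, 1e-6], [np.inf, np.inf]))
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise RuntimeError(f"Hill fit did not converge from any of the "
                           f"starting points {_HILL_STARTS}")
    a, b = best.x
    return HillFit(a_rel=float(a), b=float(b))


def build_activation_curve(records: list[TetanusRecord]) -> ActivationCurve:
    """Average normalized tetanic rises into a single activation array.

    Each record is normalized to its maximal (plateau) force -- estimated as
    the mean over the final tenth of the record, which is robust to sample
    noise where a single-sample maximum is biased high -- then records are
    truncated to the shortest (with a warning), averaged pointwise, clipped
    to [0, 1] and made non-decreasing by running maximum (the solver
    requires monotone activation); the result is rebased so it starts at
    exactly 0 and saturates at exactly 1.
    """
    if not records:
        raise ValueError("need at least one tetanus record")
    res = records[0].resolution
    n = min(r.force.size for r in records)
    if any(r.force.size != n for r in records):
        warnings.warn("tetanus records of unequal duration; truncating to "
                      "the shortest")

    def plateau(f):
        tail = f[-max(1, f.size // 10):]
        level = float(np.mean(tail))
        return level if level > 0 else float(f.max())

    stack = np.stack([r.force[:n] / plateau(r.force[:n]) for r in records])
    mean = np.clip(stack.mean(axis=0), 0.0, 1.0)
    mono = np.maximum.accumulate(mean)
    span = mono[-1] - mono[0]
    if span <= 0:
        raise ValueError("averaged tetanus record is flat")
    scaled = (mono - mono[0]) / span
    t = np.arange(n) / res
    return ActivationCurve(t, scaled)


def muscle_spec_from_fits(active_fit: PolynomialFit,
                          passive_fit: PolynomialFit, hill: HillFit,
                          activation: ActivationCurve,
                          **overrides) -> MuscleSpec:
    """Assemble a simulator-ready MuscleSpec from fitted relations."""
    kw = dict(
        active_fl_coeffs=tuple(active_fit.coeffs),
        passive_fl_coeffs=tuple(passive_fit.coeffs),
        hill_a_rel=hill.a_rel,
        hill_b=hill.b,
        activation=activation,
    )
    kw.update(overrides)
    return MuscleSpec(**kw)
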