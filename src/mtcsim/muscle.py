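"""Hill-type muscle: force--length, force--velocity and activation scaling.

Instantaneous muscle force is the maximal isometric force :math:`P_0` scaled
by three multiplicative factors -- activation (time since stimulation onset),
the active force--length relation (a cubic in percent of optimal length), and
the Hill force--velocity relation -- plus a passive force--length term that is
zero below optimal length:

.. math::

    F(t, L, V) = P_0 \\,[\\, a(t) \\cdot f_L(L) \\cdot f_V(V) \\,] + P_0 f_P(L)

All lengths are expressed as percent of the optimal length ``L0`` and all
velocities in muscle lengths per second (shortening positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ACTIVE_FL_COEFFS",
    "PASSIVE_FL_COEFFS",
    "ActivationCurve",
    "MuscleSpec",
    "active_fl_scale",
    "passive_fl_scale",
    "fv_scale",
    "activation_scale",
    "muscle_force",
    "hill_velocity_at_force",
    "hill_power_optimum",
]

#: Cubic coefficients (c0..c3, argument in %L0) of the normalized active
#: force--length regression fitted to pooled frog sartorius data.
ACTIVE_FL_COEFFS: tuple[float, float, float, float] = (-5.88, 0.151, -9.54e-4, 1.37e-6)

#: Cubic coefficients of the normalized passive force--length regression.
PASSIVE_FL_COEFFS: tuple[float, float, float, float] = (-3.72, 0.125, -1.38e-3, 5.07e-6)


def _poly3(coeffs: Sequence[float], x):
    c0, c1, c2, c3 = coeffs
    return c0 + x * (c1 + x * (c2 + x * c3))


@dataclass(frozen=True)
class ActivationCurve:
    """Force--time (activation) relation: scale in [0, 1] vs seconds.

    Samples are uniformly spaced (``resolution`` Hz), start at zero, rise
    monotonically and saturate at exactly 1; queries beyond the last sample
    return 1. Between samples the scale is linearly interpolated.
    """

    times: np.ndarray
    scales: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.scales, dtype=float)
        if t.ndim != 1 or t.shape != s.shape or t.size < 2:
            raise ValueError("activation curve needs matching 1-d time/scale arrays")
        if t[0] != 0.0 or s[0] != 0.0:
            raise ValueError("activation curve must start at (t=0, scale=0)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("activation times must be strictly increasing")
        if np.any(np.diff(s) < 0):
            raise ValueError("activation scales must be non-decreasing")
        if not np.isclose(s[-1], 1.0, rtol=0, atol=1e-12):
            raise ValueError("activation curve must saturate at 1")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "scales", s)

    @property
    def resolution(self) -> float:
        """Sampling rate in Hz (samples are uniformly spaced)."""
        return 1.0 / float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1])

    def scale(self, t) -> float | np.ndarray:
        """Linearly interpolated activation at time ``t`` (>= 0 s)."""
        return np.interp(t, self.times, self.scales)

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame({"time_s": self.times, "scale": self.scales}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "ActivationCurve":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df["time_s"].to_numpy(), df["scale"].to_numpy())


def _default_curve() -> ActivationCurve:
    # synthetic stand-in for the measured tetanic-rise array; see synth module
    from .synth import default_activation_curve

    return default_activation_curve()


@dataclass(frozen=True)
class MuscleSpec:
    """Contractile constants and scaling relations of the model muscle.

    Defaults describe the frog-sartorius-parameterized model muscle: 10 g,
    10 cm optimal length, density 1050 kg/m3, maximal isometric stress
    250 kPa, Hill constants a = 0.52 P0 and b = 4.17 lengths/s.
    ``reporting_vmax`` (7.60 lengths/s, the measured maximal shortening
    velocity) is used only to express load velocities as a percent of Vmax
    in reports; the dynamics use the Hill curve itself.
    """

    max_isometric_stress: float = 250e3  # Pa
    mass: float = 0.010  # kg
    rest_length: float = 0.10  # m (L0)
    density: float = 1050.0  # kg/m3
    hill_a_rel: float = 0.52  # fraction of P0
    hill_b: float = 4.17  # lengths/s
    active_fl_coeffs: tuple = ACTIVE_FL_COEFFS
    passive_fl_coeffs: tuple = PASSIVE_FL_COEFFS
    activation: ActivationCurve = field(default_factory=_default_curve)
    reporting_vmax: float = 7.60  # lengths/s
    normalize_active_fl: bool = False

    def __post_init__(self):
        for name in ("max_isometric_stress", "mass", "rest_length", "density",
                     "hill_a_rel", "hill_b", "reporting_vmax"):
            if not getattr(self, name) > 0:
                raise ValueError(f"MuscleSpec.{name} must be > 0")
        if len(self.active_fl_coeffs) != 4 or len(self.passive_fl_coeffs) != 4:
            raise ValueError("force-length relations are cubics: 4 coefficients")
        object.__setattr__(self, "active_fl_coeffs", tuple(map(float, self.active_fl_coeffs)))
        object.__setattr__(self, "passive_fl_coeffs", tuple(map(float, self.passive_fl_coeffs)))

    @property
    def cross_sectional_area(self) -> float:
        """Physiological cross-sectional area mass/(density * L0), m2."""
        return self.mass / (self.density * self.rest_length)

    @property
    def p0_force(self) -> float:
        """Maximal isometric force P0 = stress * area, N."""
        return self.max_isometric_stress * self.cross_sectional_area

    @property
    def v_zero(self) -> float:
        """Shortening velocity (lengths/s) at which the Hill force reaches 0."""
        return self.hill_b / self.hill_a_rel

    @property
    def active_fl_peak(self) -> float:
        """Peak value of the active force--length cubic (divisor when
        ``normalize_active_fl`` is set, 1.0 otherwise)."""
        if not self.normalize_active_fl:
            return 1.0
        c = self.active_fl_coeffs
        # stationary points of the cubic; pick the interior maximum
        roots = np.roots([3 * c[3], 2 * c[2], c[1]])
        roots = roots[np.isreal(roots)].real
        vals = [_poly3(c, r) for r in roots if r > 0]
        if not vals:
            raise ValueError("active force-length cubic has no interior peak")
        return float(max(vals))


def active_fl_scale(pct_L0, coeffs=ACTIVE_FL_COEFFS, peak: float = 1.0):
    """Active force--length scaling factor at ``pct_L0`` percent of L0.

    The raw cubic regression value is returned (divided by ``peak`` when
    renormalizing to the curve's maximum); the sign is *not* clamped here --
    a non-positive return marks the muscle's shortening limit and is the
    simulator's responsibility to act on.
    """
    return _poly3(coeffs, np.asarray(pct_L0, dtype=float)) / peak


def passive_fl_scale(pct_L0, coeffs=PASSIVE_FL_COEFFS):
    """Passive force--length scaling factor: zero below L0, cubic (floored
    at 0) at and above L0."""
    x = np.asarray(pct_L0, dtype=float)
    val = np.where(x < 100.0, 0.0, np.maximum(_poly3(coeffs, x), 0.0))
    return val if val.ndim else float(val)


def fv_scale(v, a_rel: float = 0.52, b: float = 4.17):
    """Hill force--velocity scaling factor, shortening velocity in lengths/s.

    Normalized Hill relation solved for force::

        P/P0 = b (1 + a_rel) / (v + b) - a_rel

    clamped to [0, 1]: 1 for lengthening (v < 0, no eccentric enhancement),
    0 beyond the unloaded shortening velocity ``b / a_rel``.
    """
    v = np.asarray(v, dtype=float)
    raw = b * (1.0 + a_rel) / (v + b) - a_rel
    out = np.where(v <= 0.0, 1.0, np.clip(raw, 0.0, 1.0))
    return out if out.ndim else float(out)


def activation_scale(curve: ActivationCurve, t):
    """Activation scaling factor at time ``t`` since stimulation onset."""
    return curve.scale(t)


def muscle_force(spec: MuscleSpec, t, pct_L0, v):
    """Total muscle force (N) at time ``t``, length ``pct_L0`` and shortening
    velocity ``v`` (lengths/s): active product term plus passive term."""
    p0 = spec.p0_force
    act = activation_scale(spec.activation, t)
    fla = np.maximum(
        active_fl_scale(pct_L0, spec.active_fl_coeffs, spec.active_fl_peak), 0.0
    )
    fv = fv_scale(v, spec.hill_a_rel, spec.hill_b)
    out = p0 * (act * fla * fv) + p0 * passive_fl_scale(pct_L0, spec.passive_fl_coeffs)
    return out if np.ndim(out) else float(out)


def hill_velocity_at_force(p_rel: float, a_rel: float = 0.52, b: float = 4.17) -> float:
    """Shortening velocity (lengths/s) at which the Hill relation delivers a
    relative force ``p_rel`` = P/P0."""
    if not 0.0 <= p_rel <= 1.0:
        raise ValueError("relative force must lie in [0, 1]")
    return b * (1.0 + a_rel) / (p_rel + a_rel) - b


def hill_power_optimum(a_rel: float = 0.52, b: float = 4.17) -> tuple[float, float]:
    """Closed-form optimum of normalized isotonic power p(v) = v * fv(v).

    Setting dp/dv = 0 for the Hill hyperbola gives
    ``v_opt = b (sqrt((1 + a)/a) - 1)``. Returns ``(v_opt, p_opt)`` in
    (lengths/s, P0 * lengths/s).
    """
    v_opt = b * (np.sqrt((1.0 + a_rel) / a_rel) - 1.0)
    p_opt = v_opt * fv_scale(v_opt, a_rel, b)
    return float(v_opt), float(p_opt)
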