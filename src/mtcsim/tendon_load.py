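"""Series tendon (Hookean spring) and gravitational point load with catch.

The tendon is massless and purely elastic: force = k * elongation with
k = E * A / L_rest. It cannot push; slack is represented by zero force.
The load is a point mass resting on the ground (it cannot fall below its
start height), optionally held by a mechanical catch for a set delay after
stimulation onset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TendonSpec",
    "LoadSpec",
    "stiffness",
    "elongation",
    "stored_energy",
]


@dataclass(frozen=True)
class TendonSpec:
    """Hookean series tendon defined by modulus, rest length and area.

    Only the stiffness ``k = E A / L`` matters dynamically: tendons with
    equal ``E A / L`` behave identically.
    """

    youngs_modulus: float  # Pa
    rest_length: float = 0.02  # m
    cross_sectional_area: float = 0.95e-6  # m2

    def __post_init__(self):
        for name in ("youngs_modulus", "rest_length", "cross_sectional_area"):
            if not getattr(self, name) > 0:
                raise ValueError(f"TendonSpec.{name} must be > 0")

    @property
    def stiffness(self) -> float:
        return self.youngs_modulus * self.cross_sectional_area / self.rest_length


@dataclass(frozen=True)
class LoadSpec:
    """Gravitational point mass with an optional catch delay (s).

    ``catch_delay = 0`` means no mechanical catch: only the load's weight and
    inertia resist the muscle.
    """

    mass: float  # kg
    gravity: float = 9.81  # m/s2
    catch_delay: float = 0.0  # s

    def __post_init__(self):
        if not self.mass > 0:
            raise ValueError("LoadSpec.mass must be > 0")
        if not self.gravity > 0:
            raise ValueError("LoadSpec.gravity must be > 0")
        if self.catch_delay < 0:
            raise ValueError("LoadSpec.catch_delay must be >= 0")

    @property
    def weight(self) -> float:
        return self.mass * self.gravity


def stiffness(spec: TendonSpec) -> float:
    """Tendon stiffness k = E * A / L_rest (N/m)."""
    return spec.stiffness


def elongation(spec: TendonSpec, force: float) -> float:
    """Elongation (m) under a tensile ``force`` (N, >= 0)."""
    if force < 0:
        raise ValueError("tendon cannot push: force must be >= 0 (slack = 0)")
    return force / spec.stiffness


def stored_energy(elongation_series, force_series) -> float:
    """Elastic energy (J) absorbed over a loading history.

    Trapezoid sum of (change in tendon length) x (average force) over each
    interval; for a linear spring this converges to the exact
    ``1/2 k (e_end^2 - e_start^2)``.
    """
    e = np.asarray(elongation_series, dtype=float)
    f = np.asarray(force_series, dtype=float)
    if e.shape != f.shape or e.ndim != 1:
        raise ValueError("elongation and force series must be equal-length 1-d")
    if e.size < 2:
        return 0.0
    return float(np.sum(np.diff(e) * (f[:-1] + f[1:]) / 2.0))
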