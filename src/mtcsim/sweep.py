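"""Two-parameter experiment grids and surface summaries.

A sweep varies two of the system's parameters over 100 increments each
(linear for initial muscle length and catch delay, geometric for everything
else), runs one simulation per grid cell, and collects lift height, peak
MTC/muscle power and muscle work surfaces. Summaries include the surface
argmax, improvements relative to a rigid-tendon (or no-catch) reference,
and the Pearson correlation between the lift-height and peak-power
surfaces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

from .muscle import MuscleSpec
from .simulate import SimConfig, run_simulation
from .tendon_load import LoadSpec, TendonSpec

__all__ = [
    "SWEEPABLE_PARAMETERS",
    "Axis",
    "SweepSpec",
    "SweepSurface",
    "make_range",
    "run_sweep",
    "surface_argmax",
    "pearson",
]

#: sweepable parameter -> required spacing
SWEEPABLE_PARAMETERS = {
    "tendon_modulus": "geometric",
    "tendon_length": "geometric",
    "tendon_area": "geometric",
    "load_mass": "geometric",
    "catch_delay": "linear",
    "initial_muscle_length_pct": "linear",
}

SURFACE_FIELDS = ("lift_height", "peak_mtc_power", "peak_muscle_power",
                  "muscle_work")


def make_range(low: float, high: float, n: int, spacing: str) -> np.ndarray:
    """Endpoint-inclusive sample points: equal differences (linear) or
    equal ratios (geometric)."""
    if not low < high:
        raise ValueError("require low < high")
    if n < 2:
        raise ValueError("require n >= 2")
    if spacing == "linear":
        return np.linspace(low, high, n)
    if spacing == "geometric":
        if low <= 0:
            raise ValueError("geometric spacing requires low > 0")
        return np.geomspace(low, high, n)
    raise ValueError(f"unknown spacing {spacing!r}")


@dataclass(frozen=True)
class Axis:
    """One sweep axis: which parameter, over what range, how sampled."""

    parameter: str
    low: float
    high: float
    n: int = 100
    spacing: str = ""

    def __post_init__(self):
        if self.parameter not in SWEEPABLE_PARAMETERS:
            raise ValueError(f"unknown sweep parameter {self.parameter!r}; "
                             f"choose from {sorted(SWEEPABLE_PARAMETERS)}")
        required = SWEEPABLE_PARAMETERS[self.parameter]
        spacing = self.spacing or required
        if spacing != required:
            raise ValueError(f"{self.parameter} must use {required} spacing")
        object.__setattr__(self, "spacing", spacing)
        make_range(self.low, self.high, self.n, spacing)  # validate

    @property
    def values(self) -> np.ndarray:
        return make_range(self.low, self.high, self.n, self.spacing)


@dataclass(frozen=True)
class SweepSpec:
    """Two axes plus the base specs every cell shares."""

    axis1: Axis
    axis2: Axis
    muscle: MuscleSpec = field(default_factory=MuscleSpec)
    tendon: TendonSpec = field(default_factory=lambda: TendonSpec(1.5e9))
    load: LoadSpec = field(default_factory=lambda: LoadSpec(0.485))
    sim: SimConfig = field(default_factory=lambda: SimConfig(record_trace=False))

    def __post_init__(self):
        if self.axis1.parameter == self.axis2.parameter:
            raise ValueError("sweep axes must differ")


def _apply(param: str, value: float, tendon: TendonSpec, load: LoadSpec,
           cfg: SimConfig) -> tuple[TendonSpec, LoadSpec, SimConfig]:
    if param == "tendon_modulus":
        return replace(tendon, youngs_modulus=value), load, cfg
    if param == "tendon_length":
        return replace(tendon, rest_length=value), load, cfg
    if param == "tendon_area":
        return replace(tendon, cross_sectional_area=value), load, cfg
    if param == "load_mass":
        return tendon, replace(load, mass=value), cfg
    if param == "catch_delay":
        return tendon, replace(load, catch_delay=value), cfg
    if param == "initial_muscle_length_pct":
        return tendon, load, replace(cfg, initial_muscle_length_pct=value)
    raise ValueError(param)


@dataclass
class SweepSurface:
    """Result grids of a sweep (axis1 along rows, axis2 along columns).

    Failed cells hold NaN and are listed in ``failures`` with diagnostics.
    """

    spec: SweepSpec
    axis1_values: np.ndarray
    axis2_values: np.ndarray
    lift_height: np.ndarray
    peak_mtc_power: np.ndarray
    peak_muscle_power: np.ndarray
    muscle_work: np.ndarray
    failures: list = field(default_factory=list)

    def field_values(self, name: str) -> np.ndarray:
        if name not in SURFACE_FIELDS:
            raise ValueError(f"unknown surface field {name!r}")
        return getattr(self, name)

    def to_dataframe(self) -> pd.DataFrame:
        a1 = np.repeat(self.axis1_values, self.axis2_values.size)
        a2 = np.tile(self.axis2_values, self.axis1_values.size)
        return pd.DataFrame({
            self.spec.axis1.parameter: a1,
            self.spec.axis2.parameter: a2,
            "lift_height_m": self.lift_height.ravel(),
            "peak_mtc_power_W": self.peak_mtc_power.ravel(),
            "peak_muscle_power_W": self.peak_muscle_power.ravel(),
            "muscle_work_J": self.muscle_work.ravel(),
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def run_sweep(spec: SweepSpec) -> SweepSurface:
    """One deterministic simulation per grid cell (axis values are the exact
    sample points, no midpoint sampling)."""
    v1 = spec.axis1.values
    v2 = spec.axis2.values
    shape = (v1.size, v2.size)
    grids = {f: np.full(shape, np.nan) for f in SURFACE_FIELDS}
    failures = []
    for i, x1 in enumerate(v1):
        log.info("sweep row %d/%d: %s = %.6g", i + 1, v1.size,
                 spec.axis1.parameter, x1)
        tendon1, load1, cfg1 = _apply(spec.axis1.parameter, x1, spec.tendon,
                                      spec.load, spec.sim)
        for j, x2 in enumerate(v2):
            tendon, load, cfg = _apply(spec.axis2.parameter, x2, tendon1,
                                       load1, cfg1)
            try:
                _, res = run_simulation(spec.muscle, tendon, load, cfg)
            except (RuntimeError, ValueError) as err:
                failures.append(((i, j), (x1, x2), str(err)))
                continue
            grids["lift_height"][i, j] = res.apex_height
            grids["peak_mtc_power"][i, j] = res.peak_mtc_power
            grids["peak_muscle_power"][i, j] = res.peak_muscle_power
            grids["muscle_work"][i, j] = res.total_muscle_work
    return SweepSurface(spec=spec, axis1_values=v1, axis2_values=v2,
                        failures=failures, **grids)


def surface_argmax(surface: SweepSurface, field: str = "lift_height"
                   ) -> tuple[float, float, float]:
    """Grid-cell maximizer ``(axis1 value, axis2 value, max value)``.

    Ties break toward the lexicographically smallest (row, column) index.
    """
    vals = surface.field_values(field)
    if np.all(np.isnan(vals)):
        raise ValueError("surface has no successful cells")
    flat = np.nanargmax(vals)  # first occurrence = lexicographic tie-break
    i, j = np.unravel_index(flat, vals.shape)
    return (float(surface.axis1_values[i]), float(surface.axis2_values[j]),
            float(vals[i, j]))


def pearson(a, b, drop_nan: bool = True) -> float:
    """Pearson product-moment correlation over all grid cells."""
    x = np.ravel(np.asarray(a, float))
    y = np.ravel(np.asarray(b, float))
    if x.size != y.size:
        raise ValueError("surfaces must have equal cell counts")
    if drop_nan:
        keep = ~(np.isnan(x) | np.isnan(y))
        x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)
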