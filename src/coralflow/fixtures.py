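"""Synthetic fixtures: analytic velocity fields and morphometric tables.

The analytic fields are exact, divergence-free flows used as oracles when
testing the leakiness metrics, interpolation and agent transport without
running the solver: a uniform stream, a linear shear, a plane-channel
(Poiseuille) profile across the periodic direction, and potential flow past a
circular cylinder extruded along its axis.  The morphometric generator draws
gap/diameter/height records from the measured ranges of real gorgonians at
each structural level; the draws are uniform over those ranges, a synthetic
stand-in for the unpublished raw measurement tables, not an inference about
their distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .geometry import CylinderArrayCell, FiniteCylinder, ObstacleSet
from .solver import FlowField

__all__ = ["AnalyticField", "make_analytic_field", "make_morphometric_table"]


@dataclass(frozen=True)
class AnalyticField:
    """A closed-form velocity field with an exact point evaluator."""

    kind: str
    parameters: dict
    evaluate: Callable[[np.ndarray], np.ndarray]

    def to_flow_field(
        self,
        cell: CylinderArrayCell | None = None,
        grid: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
        resolution: tuple[int, int, int] = (24, 48, 32),
        inlet_speed: float | None = None,
    ) -> FlowField:
        """Sample the closed form on a rectilinear grid of cell centres."""
        if grid is None:
            if cell is None:
                raise ValueError("give either a cell or an explicit grid")
            nx, ny, nz = resolution
            x = (np.arange(nx) + 0.5) * cell.cell_width / nx
            y = (np.arange(ny) + 0.5) * cell.domain_length / ny
            z = (np.arange(nz) + 0.5) * cell.domain_height / nz
        else:
            x, y, z = (np.asarray(a, dtype=float) for a in grid)
        X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        vel = self.evaluate(pts).reshape(len(x), len(y), len(z), 3)
        solid = np.zeros(vel.shape[:3], dtype=bool)
        obstacles = None
        if self.kind == "extruded_potential_cylinder":
            cyl = FiniteCylinder(
                center_x=self.parameters["center"][0],
                center_y=self.parameters["center"][1],
                z0=-np.inf,
                z1=np.inf,
                radius=self.parameters["radius"],
            )
            r = np.hypot(X - cyl.center_x, Y - cyl.center_y)
            solid = r <= cyl.radius
            if cell is not None:
                obstacles = ObstacleSet(solids=(cyl,), cell=cell)
        U = inlet_speed if inlet_speed is not None else self.parameters.get("U", 1.0)
        return FlowField(
            x=x,
            y=y,
            z=z,
            velocity=vel,
            pressure=np.zeros(vel.shape[:3]),
            solid=solid,
            inlet_speed=U,
            x_period=cell.cell_width if cell is not None else 0.0,
            cell=cell,
            convergence={"mode": f"analytic:{self.kind}", "converged": True},
            obstacles=obstacles,
        )


def _uniform(params: Mapping) -> AnalyticField:
    U = float(params.get("U", 1.0))

    def ev(pts: np.ndarray) -> np.ndarray:
        out = np.zeros((len(pts), 3))
        out[:, 1] = U
        return out

    return AnalyticField("uniform", {"U": U}, ev)


def _linear_shear(params: Mapping) -> AnalyticField:
    # streamwise speed varying linearly with height: v_y = base + rate * z
    rate = float(params.get("rate", 1.0))
    base = float(params.get("base", 0.0))

    def ev(pts: np.ndarray) -> np.ndarray:
        out = np.zeros((len(pts), 3))
        out[:, 1] = base + rate * pts[:, 2]
        return out

    return AnalyticField("linear_shear", {"rate": rate, "base": base}, ev)


def _plane_channel(params: Mapping) -> AnalyticField:
    # Poiseuille profile across x with walls at x=0 and x=width:
    # v_y = 4 u0 (x/W)(1 - x/W); channel average is (2/3) u0
    u0 = float(params.get("u0", 1.0))
    width = float(params["width"])

    def ev(pts: np.ndarray) -> np.ndarray:
        out = np.zeros((len(pts), 3))
        xi = pts[:, 0] / width
        out[:, 1] = 4.0 * u0 * xi * (1.0 - xi)
        return out

    return AnalyticField("plane_channel", {"u0": u0, "width": width}, ev)


def _potential_cylinder(params: Mapping) -> AnalyticField:
    # potential flow (speed U in +y) past a circular cylinder of radius R,
    # extruded along z; exactly zero normal velocity on r = R, zero inside
    U = float(params.get("U", 1.0))
    R = float(params["radius"])
    cx, cy = params["center"]

    def ev(pts: np.ndarray) -> np.ndarray:
        x = pts[:, 0] - cx
        y = pts[:, 1] - cy
        r2 = x * x + y * y
        out = np.zeros((len(pts), 3))
        outside = r2 > R * R
        r4 = np.where(outside, r2 * r2, 1.0)
        out[:, 0] = np.where(outside, -2.0 * U * R * R * x * y / r4, 0.0)
        out[:, 1] = np.where(outside, U * (1.0 + R * R * (x * x - y * y) / r4), 0.0)
        return out

    return AnalyticField(
        "extruded_potential_cylinder", {"U": U, "radius": R, "center": (cx, cy)}, ev
    )


_KINDS = {
    "uniform": _uniform,
    "linear_shear": _linear_shear,
    "plane_channel": _plane_channel,
    "extruded_potential_cylinder": _potential_cylinder,
}


def make_analytic_field(
    kind: str,
    parameters: Mapping | None = None,
    cell: CylinderArrayCell | None = None,
    grid: tuple | None = None,
    resolution: tuple[int, int, int] = (24, 48, 32),
) -> FlowField:
    """Discretize one of the closed-form fields onto a FlowField.

    Use :func:`analytic_field` for the un-discretized evaluator.
    """
    return analytic_field(kind, parameters).to_flow_field(
        cell=cell, grid=grid, resolution=resolution
    )


def analytic_field(kind: str, parameters: Mapping | None = None) -> AnalyticField:
    """The closed-form evaluator for an analytic field kind."""
    try:
        maker = _KINDS[kind]
    except KeyError:
        raise ValueError(f"unknown analytic field kind {kind!r}") from None
    return maker(parameters or {})


#: (G/D range, H/D range, diameter range with unit) per structural level.
_MORPHO_RANGES = {
    "branch": {"g_over_d": (1.3, 4.0), "h_over_d": (4.5, 30.0), "diameter": (0.05, 0.3), "unit": "cm"},
    "tentacle": {"g_over_d": (1.75, 3.0), "h_over_d": (8.0, 12.0), "diameter": (20.0, 80.0), "unit": "pixel"},
    "pinnule": {"g_over_d": (1.25, 2.5), "h_over_d": (8.0, 12.0), "diameter": (4.0, 15.0), "unit": "pixel"},
}


def make_morphometric_table(
    n_specimens: int,
    level: str = "branch",
    seed: int = 0,
    measurements_per_specimen: int = 5,
) -> pd.DataFrame:
    """Synthetic gap/diameter/height records emulating field measurements.

    Each specimen contributes ``measurements_per_specimen`` rows whose ratios
    are drawn uniformly from the level's observed range, so per-specimen mean
    ratios always fall inside that range.  Reproducible under ``seed``.
    """
    if n_specimens < 1:
        raise ValueError("need at least one specimen")
    try:
        ranges = _MORPHO_RANGES[level]
    except KeyError:
        raise ValueError(f"unknown level {level!r}") from None
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_specimens):
        for m in range(measurements_per_specimen):
            d = rng.uniform(*ranges["diameter"])
            gd = rng.uniform(*ranges["g_over_d"])
            hd = rng.uniform(*ranges["h_over_d"])
            rows.append(
                {
                    "specimen": f"{level}_{s:02d}",
                    "measurement": m,
                    "diameter": d,
                    "gap": gd * d,
                    "height": hd * d,
                    "unit": ranges["unit"],
                }
            )
    return pd.DataFrame(rows)
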