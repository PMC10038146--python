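"""Agent-based plankton transport and capture through the tiled cylinder array.

Plankton are modelled as point agents advected by the local fluid velocity
with an added unbiased Brownian motion representing active swimming
(effective diffusivity ~2.5e-3 cm^2 s^-1 for brine-shrimp-like plankton).
Positions follow the Euler-Maruyama scheme

    x_{n+1} = x_n + u(x_n) dt + sqrt(v dt) N(0, 1)   per axis,

where ``v`` is the per-axis displacement variance per unit time.  An agent is
captured the moment its straight-line step segment touches a cylinder surface
(continuous segment test, side and caps), exits when it crosses the outlet,
wraps periodically in x and reflects at the inlet plane and at the free-slip
top/bottom faces.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .dimensionless import speed_for_nominal_reynolds
from .geometry import FluidProperties, ObstacleSet, SEAWATER, make_branch_cell
from .solver import FlowField, SolverSettings, solve_steady

__all__ = [
    "AgentParams",
    "AgentEnsemble",
    "CaptureResult",
    "CaptureCheck",
    "tile_field",
    "step_agents",
    "detect_capture",
    "run_capture_experiment",
    "capture_table",
]

log = logging.getLogger(__name__)

STATUS_ACTIVE = _kernels.STATUS_ACTIVE
STATUS_CAPTURED = _kernels.STATUS_CAPTURED
STATUS_EXITED = _kernels.STATUS_EXITED


@dataclass
class AgentParams:
    """Parameters of one capture simulation.

    ``motion_variance`` is interpreted per ``variance_convention``:
    ``"variance"`` (default) treats it as the per-axis displacement variance
    accumulated per unit time (increment s.d. ``sqrt(v dt)``);
    ``"diffusivity"`` treats it as a diffusion coefficient d with
    ``Var = 2 d t`` per axis.  The study's plankton motility number 2.5e-3
    cm^2 s^-1 doubles as an effective diffusivity, so both conventions are
    exposed.
    """

    n_agents: int = 1000
    n_reps: int = 100
    motion_variance: float = 2.5e-3  # cm^2 s^-1
    variance_convention: str = "variance"  # or "diffusivity"
    dt: float = 0.01  # s
    max_time: float | None = None  # s; default 3 * domain_length / U
    sheet_x: tuple[float, float] = (0.4, 3.2)
    sheet_y: float = 1.0
    sheet_z: tuple[float, float] = (0.6, 3.4)
    chunk_steps: int = 250
    early_exit: bool = True
    retire_margin: float = 1.0  # cm past the obstacles before early retirement

    def __post_init__(self) -> None:
        if self.motion_variance < 0:
            raise ValueError("motion variance must be non-negative")
        if self.dt <= 0:
            raise ValueError("time step must be positive")
        if self.n_agents < 1 or self.n_reps < 1:
            raise ValueError("need at least one agent and one replicate")

    @property
    def variance_rate(self) -> float:
        """Per-axis displacement variance per unit time (cm^2 s^-1)."""
        if self.variance_convention == "diffusivity":
            return 2.0 * self.motion_variance
        return self.motion_variance


@dataclass
class AgentEnsemble:
    """Positions and per-agent status of one replicate."""

    positions: np.ndarray  # (n, 3) cm
    status: np.ndarray  # int8: 0 active, 1 captured, 2 exited
    elapsed: float = 0.0

    @classmethod
    def initialize(cls, params: AgentParams, rng: np.random.Generator) -> "AgentEnsemble":
        n = params.n_agents
        pos = np.empty((n, 3))
        pos[:, 0] = rng.uniform(*params.sheet_x, size=n)
        pos[:, 1] = params.sheet_y
        pos[:, 2] = rng.uniform(*params.sheet_z, size=n)
        return cls(positions=pos, status=np.zeros(n, dtype=np.int8))

    @property
    def n_active(self) -> int:
        return int(np.sum(self.status == STATUS_ACTIVE))

    @property
    def capture_fraction(self) -> float:
        return float(np.mean(self.status == STATUS_CAPTURED))


@dataclass(frozen=True)
class CaptureResult:
    """Capture-fraction statistics of one (G/D, Re) combination."""

    g_over_d: float
    re_nominal: float
    U: float
    seed: int
    fractions: tuple  # per-replicate capture fractions
    mean_fraction: float
    sd_fraction: float


def tile_field(field: FlowField, target_width: float) -> FlowField:
    """Repeat a periodic cell field in x to approximately ``target_width``.

    The tile count is ``round(target_width / cell_width)`` and the realised
    width ``n * cell_width`` is recorded in ``x_period``.
    """
    w = field.x_period
    n = int(round(target_width / w))
    if n < 1:
        raise ValueError(
            f"target width {target_width} is below one cell width {w}"
        )
    x = np.concatenate([field.x + m * w for m in range(n)])
    vel = np.concatenate([field.velocity] * n, axis=0)
    pres = np.concatenate([field.pressure] * n, axis=0)
    solid = np.concatenate([field.solid] * n, axis=0)
    return FlowField(
        x=x,
        y=field.y,
        z=field.z,
        velocity=vel,
        pressure=pres,
        solid=solid,
        inlet_speed=field.inlet_speed,
        x_period=n * w,
        cell=field.cell,
        fluid=field.fluid,
        convergence=dict(field.convergence),
        n_tiles=n * field.n_tiles,
        obstacles=field.obstacles,
    )


def _cylinder_args(field: FlowField):
    """Kernel arguments describing the (tiled) cylinder pattern."""
    cell = field.cell
    if cell is None:
        return 0.0, 1.0, -1.0, 0.0, 0.0, 0.0  # radius <= 0: no obstacles
    return (
        cell.axis_x,
        cell.cell_width,
        cell.radius,
        cell.axis_y,
        cell.z_bottom,
        cell.z_top,
    )


def step_agents(
    ensemble: AgentEnsemble,
    field: FlowField,
    params: AgentParams,
    n_steps: int = 1,
    rng: np.random.Generator | None = None,
    y_retire: float = np.inf,
) -> AgentEnsemble:
    """Advance the ensemble ``n_steps`` Euler-Maruyama steps (in place)."""
    if field.x_period <= 0:
        raise ValueError("agent transport needs a field periodic in x")
    if rng is None:
        rng = np.random.default_rng()
    sig = math.sqrt(params.variance_rate * params.dt)
    step_len = field.inlet_speed * params.dt + 4.0 * sig
    if field.cell is not None and step_len > field.cell.diameter / 2.0:
        warnings.warn(
            "step length exceeds D/2; collision detection may skip contacts",
            RuntimeWarning,
            stacklevel=2,
        )
    ly = field.y[-1] + (field.y[-1] - field.y[-2]) / 2.0
    lz = field.z[-1] + (field.z[-1] - field.z[-2]) / 2.0
    ax0, w, radius, ay, cz0, cz1 = _cylinder_args(field)
    done = 0
    while done < n_steps:
        chunk = min(params.chunk_steps, n_steps - done)
        normals = rng.standard_normal((chunk, params.n_agents, 3))
        n_active = _kernels.advance_agents(
            ensemble.positions,
            ensemble.status,
            field.x, field.y, field.z, field.velocity, field.x_period,
            normals, params.dt, sig,
            ly, lz,
            ax0, w, radius, ay, cz0, cz1,
            y_retire,
        )
        done += chunk
        ensemble.elapsed += chunk * params.dt
        if n_active == 0:
            break
    return ensemble


@dataclass(frozen=True)
class CaptureCheck:
    captured: bool
    t: float | None = None
    contact_point: tuple | None = None


def detect_capture(
    start: Sequence[float],
    end: Sequence[float],
    obstacles: ObstacleSet,
    tol: float = 1e-9,
) -> CaptureCheck:
    """Continuous segment-versus-obstacle contact test.

    Exploits that every solid is convex, so the signed distance along the
    segment is a convex function of the parameter: a ternary search finds its
    minimum and a bisection brackets the earliest contact.  A grazing segment
    that comes within ``tol`` of a surface counts as contact.
    """
    p0 = np.asarray(start, dtype=float)
    p1 = np.asarray(end, dtype=float)
    if not np.all(np.isfinite(p0)) or not np.all(np.isfinite(p1)):
        raise ValueError("segment endpoints must be finite")
    w = obstacles.cell.cell_width
    best_t: float | None = None
    best_point = None
    for shift in (-w, 0.0, w):
        off = np.array([shift, 0.0, 0.0])
        for solid in obstacles.solids:

            def f(t: float) -> float:
                return float(solid.sdf((p0 + t * (p1 - p0) + off)[None, :])[0])

            if f(0.0) <= tol:
                return CaptureCheck(True, 0.0, tuple(p0))
            lo, hi = 0.0, 1.0
            for _ in range(80):  # ternary search on a convex profile
                m1 = lo + (hi - lo) / 3.0
                m2 = hi - (hi - lo) / 3.0
                if f(m1) <= f(m2):
                    hi = m2
                else:
                    lo = m1
            tmin = 0.5 * (lo + hi)
            if f(tmin) > tol:
                continue
            a, b = 0.0, tmin  # f(a) > tol >= f(b): bracket earliest contact
            for _ in range(60):
                mid = 0.5 * (a + b)
                if f(mid) > tol:
                    a = mid
                else:
                    b = mid
            t_hit = b
            if best_t is None or t_hit < best_t:
                best_t = t_hit
                best_point = tuple(p0 + t_hit * (p1 - p0))
    if best_t is None:
        return CaptureCheck(False)
    return CaptureCheck(True, best_t, best_point)


def _run_replicates(
    field: FlowField,
    params: AgentParams,
    seeds: Iterable[np.random.SeedSequence],
    max_time: float,
    y_retire: float,
) -> list[float]:
    n_steps_total = max(1, int(math.ceil(max_time / params.dt)))
    fractions = []
    for ss in seeds:
        rng = np.random.default_rng(ss)
        ens = AgentEnsemble.initialize(params, rng)
        step_agents(ens, field, params, n_steps=n_steps_total, rng=rng, y_retire=y_retire)
        n = params.n_agents
        assert ens.n_active + np.sum(ens.status != STATUS_ACTIVE) == n
        fractions.append(ens.capture_fraction)
    return fractions


def run_capture_experiment(
    g_over_d_values: Sequence[float],
    nominal_re_values: Sequence[float],
    params: AgentParams | None = None,
    fluid: FluidProperties = SEAWATER,
    settings: SolverSettings | None = None,
    seed: int = 0,
    target_width: float = 3.6,
    fields: dict | None = None,
) -> list[CaptureResult]:
    """Capture fractions over a (G/D, nominal Re) grid of branch cells.

    For each combination the branch-cell flow is solved (or taken from the
    ``fields`` cache, keyed ``(g_over_d, re)``), tiled across ``target_width``,
    and ``params.n_reps`` replicates of ``params.n_agents`` agents are
    released from the initial sheet with independent child seeds spawned
    deterministically from ``seed``.  Solver failures are logged and skipped.
    """
    if params is None:
        params = AgentParams()
    results: list[CaptureResult] = []
    combo = 0
    for re in nominal_re_values:
        for g in g_over_d_values:
            combo += 1
            cell = make_branch_cell(g)
            U = speed_for_nominal_reynolds(re, cell.diameter, fluid)
            try:
                base = None
                if fields is not None:
                    base = fields.get((g, re))
                if base is None:
                    base = solve_steady(cell, cell.obstacles(), U, fluid, settings)
                    if fields is not None:
                        fields[(g, re)] = base
                tiled = tile_field(base, target_width)
            except Exception as exc:
                log.warning("capture point G/D=%s Re=%s failed: %s", g, re, exc)
                continue
            max_time = params.max_time
            if max_time is None:
                max_time = 3.0 * cell.domain_length / U
            d_eff = max(params.variance_rate / 2.0, 1e-300)
            y_retire = np.inf
            if params.early_exit:
                peclet_margin = U * params.retire_margin / d_eff
                if peclet_margin > 50.0:
                    y_retire = cell.axis_y + cell.radius + params.retire_margin
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(combo,))
            seeds = ss.spawn(params.n_reps)
            fractions = _run_replicates(tiled, params, seeds, max_time, y_retire)
            arr = np.asarray(fractions)
            results.append(
                CaptureResult(
                    g_over_d=g,
                    re_nominal=re,
                    U=U,
                    seed=seed,
                    fractions=tuple(fractions),
                    mean_fraction=float(arr.mean()),
                    sd_fraction=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
                )
            )
    return results


def capture_table(results: Iterable[CaptureResult]) -> pd.DataFrame:
    """Tidy one-row-per-replicate DataFrame from capture results."""
    rows = []
    for r in results:
        for rep, frac in enumerate(r.fractions):
            rows.append(
                {
                    "g_over_d": r.g_over_d,
                    "re_nominal": r.re_nominal,
                    "U": r.U,
                    "seed": r.seed,
                    "replicate": rep,
                    "capture_fraction": frac,
                    "mean_fraction": r.mean_fraction,
                    "sd_fraction": r.sd_fraction,
                }
            )
    return pd.DataFrame(rows)
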