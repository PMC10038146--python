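"""Steady and time-resolved laminar flow in a periodic cylinder-array cell.

The incompressible Navier-Stokes equations are discretized with a staggered
finite-volume scheme on a stretched rectilinear grid (uniform in the periodic
x direction, geometrically graded in y and z away from the obstacle).  Steady
solutions are obtained by artificial-compressibility pseudo-time marching
with local time steps; time-resolved solutions use dual time stepping
(backward-Euler physical time, the same pseudo-time relaxation inside each
step).  Boundary conditions follow the unit-cell setup: uniform inflow,
zero-pressure outlet, periodic side faces and free-slip (symmetry) top and
bottom faces; obstacles are stair-step masked using the analytic
inside/outside query from :mod:`coralflow.geometry`.

Two standard accelerations keep desk-scale solves fast: when the obstacle
set is mirror-symmetric about the domain mid-height (every plain or
polyp-decorated cell is), only the bottom half is solved with the free-slip
symmetry plane at mid-height and the field is mirrored on export; and each
solve is initialized from a converged half-resolution solution interpolated
onto the fine grid.
"""

from __future__ import annotations

import copy
import time
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np

from . import _kernels
from .geometry import CylinderArrayCell, FluidProperties, ObstacleSet, SEAWATER

__all__ = [
    "SolverSettings",
    "FlowField",
    "ConvergenceError",
    "OutOfDomainError",
    "solve_steady",
    "solve_unsteady",
    "interpolate_velocity",
    "drag_force",
]


class ConvergenceError(RuntimeError):
    """Raised when the solver fails to reach the requested residual."""

    def __init__(self, message: str, residual_history: Sequence[float]):
        super().__init__(message)
        self.residual_history = list(residual_history)


class OutOfDomainError(ValueError):
    """Point lies outside the domain in a non-periodic direction."""


@dataclass
class SolverSettings:
    """Numerical parameters for the cell solver.

    The grid is controlled by ``n_per_diameter`` (cells across one cylinder
    diameter in the refined region; at least 8), ``axial_coarsen`` (spacing
    along the cylinder span relative to the fine spacing) and ``max_coarsen``
    (coarsest spacing far from the obstacle relative to the fine spacing).
    ``tolerance`` is the nondimensional steady momentum residual
    ``||du/dtau||_rms * D / U^2``; ``div_tolerance`` bounds the cell-wise
    divergence scaled by the local cell size, relative to the inlet speed.
    """

    n_per_diameter: int = 8
    axial_coarsen: float = 4.0
    max_coarsen: float = 24.0
    growth: float = 0.3  # spacing growth per unit distance from a fine window
    tolerance: float = 1e-3
    div_tolerance: float = 3e-4
    max_iters: int = 40000
    cfl: float = 0.9
    beta: float | None = None  # artificial compressibility (cm^2 s^-2); auto
    mask_inflate: float = 0.0  # x local h; >0 keeps thin solids watertight
    check_interval: int = 250
    allow_plateau: bool = True
    plateau_factor: float = 10.0
    convection: str = "central"  # or "hybrid" (first-order upwind at Pe>2)
    use_z_symmetry: bool = True
    coarse_init: bool = True
    coarse_tol_factor: float = 30.0
    inner_tolerance_factor: float = 8.0  # dual-time inner loop relative tol
    max_inner: int = 600

    def __post_init__(self) -> None:
        if self.n_per_diameter < 8:
            raise ValueError("need at least 8 cells across one diameter")
        if self.tolerance <= 0 or self.div_tolerance <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class FlowField:
    """Velocity/pressure solution sampled at cell centres of a rectilinear grid.

    ``velocity`` has shape (nx, ny, nz, 3) in cm s^-1 with components ordered
    (x, y, z); samples inside obstacles are exactly zero.  ``x`` is periodic
    with period ``x_period`` (the cell width, or the tiled width after
    :func:`coralflow.agents.tile_field`).
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    velocity: np.ndarray
    pressure: np.ndarray
    solid: np.ndarray
    inlet_speed: float
    x_period: float
    cell: CylinderArrayCell | None = None
    fluid: FluidProperties | None = None
    convergence: dict = dc_field(default_factory=dict)
    n_tiles: int = 1
    obstacles: ObstacleSet | None = None

    @property
    def shape(self) -> tuple:
        return self.velocity.shape[:3]

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Trilinear velocity interpolation at (n, 3) points (periodic in x)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        ymax = self.y[-1] + (self.y[-1] - self.y[-2])
        zmax = self.z[-1] + (self.z[-1] - self.z[-2])
        if np.any(pts[:, 1] < -1e-12) or np.any(pts[:, 1] > ymax + 1e-12):
            raise OutOfDomainError("point outside domain in y")
        if np.any(pts[:, 2] < -1e-12) or np.any(pts[:, 2] > zmax + 1e-12):
            raise OutOfDomainError("point outside domain in z")
        return _kernels.interp_many(
            self.x, self.y, self.z, self.velocity, self.x_period, pts
        )


# ---------------------------------------------------------------------------
# grid generation
# ---------------------------------------------------------------------------


def _build_axis(total: float, windows: list, h_max: float, growth: float) -> np.ndarray:
    """Face coordinates on [0, total] honouring fine windows.

    Desired spacing at x is the minimum over windows of
    ``h_window + growth * distance_to_window`` (linear growth is equivalent to
    geometric stretching with ratio ``1 + growth``), capped at ``h_max``.
    """

    def hdes(q: float) -> float:
        h = h_max
        for lo, hi, hw in windows:
            d = lo - q if q < lo else (q - hi if q > hi else 0.0)
            h = min(h, hw + growth * d)
        return h

    faces = [0.0]
    while faces[-1] < total:
        faces.append(faces[-1] + hdes(faces[-1]))
        if len(faces) > 100000:
            raise RuntimeError("axis generation runaway; check spacing parameters")
    arr = np.asarray(faces)
    arr = arr * (total / arr[-1])
    return arr


def build_grid(
    cell: CylinderArrayCell,
    obstacles: ObstacleSet,
    settings: SolverSettings,
    half: bool = False,
):
    """Cell-centre coordinates and spacings; ``half`` solves z in [0, H/2]."""
    h_fine = cell.diameter / settings.n_per_diameter
    w = cell.cell_width
    # the gap jet needs several cells across it even when G < D
    h_fine_x = min(h_fine, cell.gap / 5.0) if not obstacles.is_empty() else h_fine
    nx = max(8, int(round(w / h_fine_x / 2.0)) * 2)
    dx = w / nx
    xc = (np.arange(nx) + 0.5) * dx

    bbox = obstacles.bbox()
    d = cell.diameter
    h_max = h_fine * settings.max_coarsen
    z_extent = cell.domain_height / 2.0 if half else cell.domain_height
    if bbox is None:
        yf = _build_axis(cell.domain_length, [], min(h_max, cell.domain_length / 8), settings.growth)
        zf = _build_axis(z_extent, [], min(h_max, z_extent / 4), settings.growth)
    else:
        _, _, ymin, ymax, zmin, zmax = bbox
        ywin = [(ymin - 1.2 * d, ymax + 2.0 * d, h_fine)]
        yf = _build_axis(cell.domain_length, ywin, min(h_max, cell.domain_length / 10), settings.growth)
        zwin = [(zmin - d, zmin + d, h_fine)]
        if half:
            zwin.append((zmin, z_extent, h_fine * settings.axial_coarsen))
        else:
            zwin.append((zmax - d, zmax + d, h_fine))
            zwin.append((zmin, zmax, h_fine * settings.axial_coarsen))
        zf = _build_axis(z_extent, zwin, min(h_max, z_extent / 6), settings.growth)
    yc = 0.5 * (yf[:-1] + yf[1:])
    zc = 0.5 * (zf[:-1] + zf[1:])
    return dict(
        xc=xc, yc=yc, zc=zc,
        dy=np.diff(yf), dz=np.diff(zf),
        yf=yf, zf=zf, dx=dx, half=half,
    )


def _face_masks(solid_p: np.ndarray):
    """Solid masks for the staggered velocity faces from the cell mask."""
    nx, ny, nz = solid_p.shape
    solid_u = solid_p | np.roll(solid_p, 1, axis=0)
    solid_v = np.zeros((nx, ny + 1, nz), dtype=np.bool_)
    solid_v[:, 1:ny, :] = solid_p[:, 1:, :] | solid_p[:, :-1, :]
    solid_w = np.zeros((nx, ny, nz + 1), dtype=np.bool_)
    solid_w[:, :, 1:nz] = solid_p[:, :, 1:] | solid_p[:, :, :-1]
    return solid_u, solid_v, solid_w


def _z_symmetric(obstacles: ObstacleSet, cell: CylinderArrayCell) -> bool:
    """Is the obstacle set mirror-symmetric about the domain mid-height?"""
    if obstacles.is_empty():
        return True
    rng = np.random.default_rng(12345)
    pts = rng.uniform(
        low=(0.0, 0.0, 0.0),
        high=(cell.cell_width, cell.domain_length, cell.domain_height),
        size=(128, 3),
    )
    mirrored = pts.copy()
    mirrored[:, 2] = cell.domain_height - mirrored[:, 2]
    return bool(np.max(np.abs(obstacles.sdf(pts) - obstacles.sdf(mirrored))) < 1e-8)


# ---------------------------------------------------------------------------
# solve drivers
# ---------------------------------------------------------------------------


def _auto_beta(U: float, nu: float, h_fine: float) -> float:
    """Artificial compressibility: the pseudo sound speed must outrun both the
    flow (~2U through the gaps) and the diffusive signal speed nu/h."""
    return max((2.5 * U) ** 2, (3.0 * nu / h_fine) ** 2)


def _prepare(cell, obstacles, U, fluid, settings, half):
    if U < 0:
        raise ValueError("inlet speed must be non-negative")
    grid = build_grid(cell, obstacles, settings, half=half)
    h_fine = cell.diameter / settings.n_per_diameter
    xc, yc, zc = grid["xc"], grid["yc"], grid["zc"]
    if obstacles.is_empty():
        solid_p = np.zeros((len(xc), len(yc), len(zc)), dtype=np.bool_)
    else:
        inflate = settings.mask_inflate * h_fine
        solid_p = obstacles.mask(xc, yc, zc, inflate=inflate)
    solid_u, solid_v, solid_w = _face_masks(solid_p)
    nx, ny, nz = solid_p.shape
    u = np.zeros((nx, ny, nz))
    v = np.full((nx, ny + 1, nz), float(U))
    w = np.zeros((nx, ny, nz + 1))
    p = np.zeros((nx, ny, nz))
    u[solid_u] = 0.0
    v[solid_v] = 0.0
    nu = fluid.kinematic_viscosity
    beta = settings.beta if settings.beta is not None else _auto_beta(U, nu, h_fine)
    return grid, (solid_p, solid_u, solid_v, solid_w), (u, v, w, p), nu, beta


def _init_from_field(grid, masks, state, coarse: FlowField) -> None:
    """Initialize the staggered state by interpolating a coarser solution."""
    solid_p, solid_u, solid_v, solid_w = masks
    u, v, w, p = state
    xc, yc, zc = grid["xc"], grid["yc"], grid["zc"]
    yf, zf, dx = grid["yf"], grid["zf"], grid["dx"]
    nx, ny, nz = solid_p.shape
    xf = np.arange(nx) * dx

    def sample(px, py, pz):
        X, Y, Z = np.meshgrid(px, py, pz, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        return coarse.interpolate(pts).reshape(len(px), len(py), len(pz), 3)

    u[...] = sample(xf, yc, zc)[..., 0]
    v[...] = sample(xc, yf, zc)[..., 1]
    w[...] = sample(xc, yc, zf)[..., 2]
    # pressure through the same trilinear kernel, packed as a vector field
    pvec = np.zeros(coarse.velocity.shape)
    pvec[..., 0] = coarse.pressure
    pf = FlowField(
        x=coarse.x, y=coarse.y, z=coarse.z, velocity=pvec,
        pressure=coarse.pressure, solid=coarse.solid,
        inlet_speed=coarse.inlet_speed, x_period=coarse.x_period,
    )
    X, Y, Z = np.meshgrid(xc, yc, zc, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    p[...] = pf.interpolate(pts)[:, 0].reshape(nx, ny, nz)
    u[solid_u] = 0.0
    v[solid_v] = 0.0
    w[solid_w] = 0.0
    v[:, 0, :] = coarse.inlet_speed
    w[:, :, 0] = 0.0
    w[:, :, -1] = 0.0
    p[solid_p] = 0.0


def _export_field(grid, masks, state, cell, obstacles, U, fluid, convergence) -> FlowField:
    solid_p, _, _, _ = masks
    u, v, w, p = state
    vel = np.zeros(solid_p.shape + (3,))
    vel[..., 0] = 0.5 * (u + np.roll(u, -1, axis=0))
    vel[..., 1] = 0.5 * (v[:, :-1, :] + v[:, 1:, :])
    vel[..., 2] = 0.5 * (w[:, :, :-1] + w[:, :, 1:])
    vel[solid_p] = 0.0
    pressure = p.copy()
    solid = solid_p.copy()
    zc = grid["zc"].copy()
    if grid["half"]:
        # mirror the half-height solution through the symmetry plane
        z_top = cell.domain_height
        zc = np.concatenate([zc, z_top - grid["zc"][::-1]])
        vel_m = vel[:, :, ::-1, :].copy()
        vel_m[..., 2] *= -1.0
        vel = np.concatenate([vel, vel_m], axis=2)
        pressure = np.concatenate([pressure, pressure[:, :, ::-1]], axis=2)
        solid = np.concatenate([solid, solid[:, :, ::-1]], axis=2)
    return FlowField(
        x=grid["xc"].copy(),
        y=grid["yc"].copy(),
        z=zc,
        velocity=vel,
        pressure=pressure,
        solid=solid,
        inlet_speed=U,
        x_period=cell.cell_width,
        cell=cell,
        fluid=fluid,
        convergence=convergence,
        obstacles=obstacles,
    )


def _reynolds_guard(cell, U, fluid):
    re_nominal = U * cell.diameter / fluid.nominal_kinematic_viscosity
    if re_nominal > 220.0:
        warnings.warn(
            f"nominal Re = {re_nominal:.0f} is beyond the laminar range the "
            "scheme is validated for; results may be unreliable",
            RuntimeWarning,
            stacklevel=3,
        )


def _diagnostics(state, grid, masks, fluid, U):
    u, v, w, p = state
    solid_p = masks[0]
    fluxes = _kernels.section_fluxes(v, grid["dx"], grid["dz"])
    inlet_flux = float(fluxes[0])
    scale = 2.0 if grid["half"] else 1.0  # report full-domain totals
    return {
        "inlet_flux": scale * inlet_flux,
        "outlet_flux": scale * float(fluxes[-1]),
        "max_flux_deviation": float(np.max(np.abs(fluxes - inlet_flux)))
        / max(abs(inlet_flux), 1e-300),
        "n_cells": int(solid_p.size),
    }


def _march_steady(grid, masks, state, nu, beta, fluid, U, diameter, settings):
    """Pseudo-time march to steady state; returns (state, history, info)."""
    u, v, w, p = state
    un, vn, wn = u.copy(), v.copy(), w.copy()
    solid_p, solid_u, solid_v, solid_w = masks
    uref = max(U, 1e-12)
    # residual measured against the dominant force scale (inertial at high
    # Re, viscous at low Re) so Stokes-regime solves are not over-penalized
    scale = diameter / (uref**2 + nu * uref / diameter)
    dummy = np.zeros((1, 1, 1))
    history: list[float] = []
    div_rel = np.inf
    converged = False
    plateaued = False
    it = 0
    res = np.inf
    while it < settings.max_iters:
        res_sq, res_max, nfaces = _kernels.momentum_sweep(
            u, v, w, p, un, vn, wn,
            solid_u, solid_v, solid_w,
            grid["dx"], grid["yc"], grid["zc"], grid["dy"], grid["dz"],
            nu, fluid.density, beta, U,
            settings.cfl, True, 0.0,
            0.0, dummy, dummy, dummy,
            settings.convection == "central", u.shape[1] - 4,
        )
        div_scaled = _kernels.pressure_sweep(
            un, vn, wn, p, solid_p,
            grid["dx"], grid["dy"], grid["dz"],
            fluid.density, beta,
            settings.cfl, True, 0.0,
        )
        u, un = un, u
        v, vn = vn, v
        w, wn = wn, w
        it += 1
        if it % settings.check_interval == 0 or it == 1:
            res = float(np.sqrt(res_sq / max(nfaces, 1)) * scale)
            div_rel = float(div_scaled / uref)
            history.append(res)
            if not np.isfinite(res):
                raise ConvergenceError("solver diverged (non-finite residual)", history)
            if res < settings.tolerance and div_rel < settings.div_tolerance:
                converged = True
                break
            if settings.allow_plateau and len(history) >= 12:
                # stalled: no 3% improvement on the best residual over the
                # last 8 checks, and already within the acceptance band
                best = min(history)
                if (
                    min(history[-8:]) >= 0.97 * best
                    and res < settings.plateau_factor * settings.tolerance
                ):
                    plateaued = True
                    break
    else:
        if not (settings.allow_plateau and res < settings.plateau_factor * settings.tolerance):
            raise ConvergenceError(
                f"no steady state within {settings.max_iters} iterations "
                f"(residual {res:.3g})",
                history,
            )
        plateaued = True
    info = {
        "residual": history[-1] if history else 0.0,
        "residual_history": history,
        "iterations": it,
        "converged": converged,
        "plateaued": plateaued,
        "div_rel": div_rel,
        "beta": beta,
    }
    return (u, v, w, p), info


def solve_steady(
    cell: CylinderArrayCell,
    obstacles: ObstacleSet | None = None,
    U: float = 1.0,
    fluid: FluidProperties = SEAWATER,
    settings: SolverSettings | None = None,
) -> FlowField:
    """March the artificial-compressibility system to a steady state.

    Returns a :class:`FlowField` whose ``convergence`` dict reports the final
    residual, iteration count, divergence level and the inlet/outlet flux
    balance.  Raises :class:`ConvergenceError` if the residual neither reaches
    ``settings.tolerance`` nor plateaus below ``plateau_factor * tolerance``.
    """
    if settings is None:
        settings = SolverSettings()
    if obstacles is None:
        obstacles = cell.obstacles()
    _reynolds_guard(cell, U, fluid)
    half = settings.use_z_symmetry and _z_symmetric(obstacles, cell)
    t0 = time.perf_counter()

    coarse_field = None
    if settings.coarse_init and settings.n_per_diameter >= 8 and not obstacles.is_empty():
        cs = copy.copy(settings)
        cs.n_per_diameter = max(4, settings.n_per_diameter // 2)
        cs.coarse_init = False
        cs.tolerance = settings.tolerance * settings.coarse_tol_factor
        cs.div_tolerance = settings.div_tolerance * settings.coarse_tol_factor
        cs.allow_plateau = True
        cs.convection = "hybrid"  # robust initializer
        cs.plateau_factor = max(cs.plateau_factor, 50.0)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                coarse_field = solve_steady(cell, obstacles, U, fluid, cs)
        except ConvergenceError:
            coarse_field = None  # fall back to a uniform initial guess

    grid, masks, state, nu, beta = _prepare(cell, obstacles, U, fluid, settings, half)
    if coarse_field is not None:
        _init_from_field(grid, masks, state, coarse_field)
    state, info = _march_steady(
        grid, masks, state, nu, beta, fluid, U, cell.diameter, settings
    )
    convergence = dict(info)
    convergence["mode"] = "steady"
    convergence["half_domain"] = half
    convergence["coarse_init"] = coarse_field is not None
    convergence["wall_time_s"] = time.perf_counter() - t0
    convergence.update(_diagnostics(state, grid, masks, fluid, U))
    if convergence["plateaued"] and not convergence["converged"]:
        warnings.warn(
            "steady residual plateaued above tolerance (limit-cycle or "
            "stair-step noise floor); returning the quasi-steady field",
            RuntimeWarning,
            stacklevel=2,
        )
    field = _export_field(grid, masks, state, cell, obstacles, U, fluid, convergence)
    field.convergence["drag"] = drag_force(field)
    return field


def solve_unsteady(
    cell: CylinderArrayCell,
    obstacles: ObstacleSet | None = None,
    U: float = 1.0,
    fluid: FluidProperties = SEAWATER,
    settings: SolverSettings | None = None,
    total_time: float | None = None,
    n_steps: int = 120,
    store_every: int = 0,
) -> tuple[FlowField, dict]:
    """Time-resolved solve by dual time stepping (backward-Euler in time).

    Starts from uniform inflow and marches ``total_time`` (default six domain
    flow-through times).  Returns the final-time field and a report whose
    ``steadiness`` entry is ``||u(t_end) - u(t_end - dt)|| / ||u||``; with
    ``store_every`` > 0 every that-many-th frame is kept under ``frames``.
    """
    if settings is None:
        settings = SolverSettings()
    if obstacles is None:
        obstacles = cell.obstacles()
    _reynolds_guard(cell, U, fluid)
    if total_time is None:
        total_time = 8.0 * cell.domain_length / U if U > 0 else 1.0
    dt = total_time / n_steps
    half = settings.use_z_symmetry and _z_symmetric(obstacles, cell)
    grid, masks, state, nu, beta = _prepare(cell, obstacles, U, fluid, settings, half)
    u, v, w, p = state
    un, vn, wn = u.copy(), v.copy(), w.copy()
    solid_p, solid_u, solid_v, solid_w = masks
    uref = max(U, 1e-12)
    scale = cell.diameter / (uref**2 + nu * uref / cell.diameter)
    inner_tol = settings.tolerance * settings.inner_tolerance_factor
    frames = []
    times = []
    t0 = time.perf_counter()
    delta_last = 0.0
    norm_last = 1.0
    total_inner = 0
    for step in range(n_steps):
        u_prev, v_prev, w_prev = u.copy(), v.copy(), w.copy()
        inner = 0
        while inner < settings.max_inner:
            res_sq, _, nfaces = _kernels.momentum_sweep(
                u, v, w, p, un, vn, wn,
                solid_u, solid_v, solid_w,
                grid["dx"], grid["yc"], grid["zc"], grid["dy"], grid["dz"],
                nu, fluid.density, beta, U,
                settings.cfl, True, 0.0,
                1.0 / dt, u_prev, v_prev, w_prev,
                settings.convection == "central", u.shape[1] - 4,
            )
            _kernels.pressure_sweep(
                un, vn, wn, p, solid_p,
                grid["dx"], grid["dy"], grid["dz"],
                fluid.density, beta,
                settings.cfl, True, 0.0,
            )
            u, un = un, u
            v, vn = vn, v
            w, wn = wn, w
            inner += 1
            if inner % 25 == 0:
                res = float(np.sqrt(res_sq / max(nfaces, 1)) * scale)
                if not np.isfinite(res):
                    raise ConvergenceError("unsteady solver diverged", [res])
                if res < inner_tol:
                    break
        total_inner += inner
        delta_last = float(
            np.sqrt(np.mean((v - v_prev) ** 2) + np.mean((u - u_prev) ** 2))
        )
        norm_last = float(np.sqrt(np.mean(v**2) + np.mean(u**2)))
        times.append((step + 1) * dt)
        if store_every and (step + 1) % store_every == 0:
            frames.append(
                _export_field(
                    grid, masks, (u, v, w, p), cell, obstacles, U, fluid,
                    {"time": (step + 1) * dt, "mode": "unsteady-frame"},
                )
            )
    steadiness = delta_last / max(norm_last, 1e-300)
    convergence = {
        "mode": "unsteady",
        "total_time": total_time,
        "dt": dt,
        "n_steps": n_steps,
        "inner_iterations": total_inner,
        "steadiness": steadiness,
        "beta": beta,
        "half_domain": half,
        "wall_time_s": time.perf_counter() - t0,
        "converged": True,
    }
    convergence.update(_diagnostics((u, v, w, p), grid, masks, fluid, U))
    final = _export_field(grid, masks, (u, v, w, p), cell, obstacles, U, fluid, convergence)
    final.convergence["drag"] = drag_force(final)
    report = {"times": times, "frames": frames, "steadiness": steadiness}
    return final, report


def interpolate_velocity(field: FlowField, point: Sequence[float]) -> np.ndarray:
    """Velocity vector at a point (trilinear; periodic in x; zero in solids)."""
    return field.interpolate(np.asarray(point, dtype=float))[0]


def drag_force(field: FlowField) -> float:
    """Streamwise force (dyn) on the obstacle by summing surface stresses on
    the stair-step solid: pressure on the upstream/downstream solid faces
    plus viscous shear on the lateral and cap faces (normal viscous stresses
    are neglected).  Local to the obstacle, so insensitive to far-field
    pressure noise; intended for convergence self-checks.
    """
    if field.fluid is None:
        raise ValueError("drag needs fluid properties on the field")
    rho = field.fluid.density
    mu = field.fluid.dynamic_viscosity
    solid = field.solid
    if not solid.any():
        return 0.0
    p = field.pressure
    vy = field.velocity[..., 1]
    x, y, z = field.x, field.y, field.z
    dx = x[1] - x[0]

    def widths(c):
        f = np.empty(len(c) + 1)
        f[1:-1] = 0.5 * (c[:-1] + c[1:])
        f[0] = c[0] - (f[1] - c[0])
        f[-1] = c[-1] + (c[-1] - f[-2])
        return np.diff(f)

    dy = widths(y)
    dz = widths(z)
    F = 0.0
    # pressure on y-normal solid faces (fluid cell pushes the solid)
    up = (~solid[:, :-1, :]) & solid[:, 1:, :]      # fluid at j, solid at j+1
    dn = solid[:, :-1, :] & (~solid[:, 1:, :])      # solid at j, fluid at j+1
    area_yz = dx * dz[None, None, :]
    F += float(np.sum(p[:, :-1, :][up] * np.broadcast_to(area_yz, up.shape)[up]))
    F -= float(np.sum(p[:, 1:, :][dn] * np.broadcast_to(area_yz, dn.shape)[dn]))
    # viscous shear from streamwise velocity gradients across x-normal walls
    nb_x = np.roll(solid, 1, axis=0) | np.roll(solid, -1, axis=0)
    lat_x = (~solid) & nb_x
    tau_x = mu * vy / (dx / 2.0)
    area_x = dy[None, :, None] * dz[None, None, :]
    F += float(np.sum((tau_x * np.broadcast_to(area_x, solid.shape))[lat_x])) / 2.0
    # and across z-normal walls (cylinder caps and tip region)
    nb_z = np.zeros_like(solid)
    nb_z[:, :, 1:] |= solid[:, :, :-1]
    nb_z[:, :, :-1] |= solid[:, :, 1:]
    lat_z = (~solid) & nb_z
    dzc = np.empty(len(z))
    dzc[1:] = z[1:] - z[:-1]
    dzc[0] = dzc[1]
    tau_z = mu * vy / (dzc[None, None, :] / 2.0)
    area_z = dx * dy[None, :, None]
    F += float(np.sum((tau_z * np.broadcast_to(area_z, solid.shape))[lat_z]))
    return F
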