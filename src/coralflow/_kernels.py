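"""Numba kernels for the flow solver and agent transport.

Staggered-grid layout (x periodic/uniform, y and z stretched):

* ``p[nx, ny, nz]`` at cell centres,
* ``u[nx, ny, nz]`` at x-faces (``u[i]`` lies between cells ``i-1`` and ``i``,
  wrapping periodically),
* ``v[nx, ny+1, nz]`` at y-faces (``v[:, 0]`` inlet, ``v[:, ny]`` outlet),
* ``w[nx, ny, nz+1]`` at z-faces (``w[..., 0]`` and ``w[..., nz]`` are the
  free-slip top/bottom faces and stay zero).

The momentum sweep advances velocities one (pseudo-)time step with hybrid
central/upwind convection and a nonuniform 3-point Laplacian; the pressure
sweep relaxes ``dp/dtau = -rho * beta * div(u)`` (artificial compressibility).
Updating velocities with the old pressure and the pressure with the new
velocities is symplectic Euler on the acoustic subsystem, which is neutrally
stable and lets the scheme march to steady state without added damping.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _hybrid(f0, fm, fp, hm, hp, a, nu, central):
    """Convective term a * df.  ``central`` keeps second-order central
    differencing everywhere (needs the advective von-Neumann bound on the
    time step); otherwise central switches to first-order upwind when the
    cell Peclet number exceeds 2 (Patankar's hybrid rule)."""
    if a == 0.0:
        return 0.0
    if not central:
        pe = abs(a) * 0.5 * (hm + hp) / nu
        if pe >= 2.0:
            if a > 0.0:
                return a * (f0 - fm) / hm
            return a * (fp - f0) / hp
    return a * (fp - fm) / (hm + hp)


@njit(cache=True, inline="always")
def _lap1(f0, fm, fp, hm, hp):
    """Nonuniform 3-point second derivative."""
    return 2.0 * ((fp - f0) / hp - (f0 - fm) / hm) / (hm + hp)


# ---------------------------------------------------------------------------
# momentum sweep
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def momentum_sweep(
    u, v, w, p,
    un, vn, wn,
    solid_u, solid_v, solid_w,
    dx, yc, zc, dy, dz,
    nu, rho, beta, u_inlet,
    cfl, local_dt, dt_fixed,
    dt_phys_inv, u_prev, v_prev, w_prev,
    central, j_outlet_upwind,
):
    """One explicit (pseudo-)time step for u, v, w into un, vn, wn.

    ``local_dt`` selects per-face pseudo-time steps (steady mode); otherwise
    ``dt_fixed`` is used everywhere.  ``dt_phys_inv`` > 0 adds the implicit
    physical-time source ``-(q - q_prev) * dt_phys_inv`` for dual-time
    stepping (zero in steady mode).
    """
    nx, ny, nz = u.shape
    c = np.sqrt(beta)
    res_sq = 0.0
    res_max = 0.0
    nfaces = 0

    # ----- u (x-faces) -----
    for i in range(nx):
        im = i - 1 if i > 0 else nx - 1
        ip = i + 1 if i < nx - 1 else 0
        for j in range(ny):
            for k in range(nz):
                if solid_u[i, j, k]:
                    un[i, j, k] = 0.0
                    continue
                u0 = u[i, j, k]
                uxm = u[im, j, k]
                uxp = u[ip, j, k]
                if j > 0:
                    uym = u[i, j - 1, k]
                    hym = yc[j] - yc[j - 1]
                else:
                    uym = -u0
                    hym = 2.0 * yc[0]
                if j < ny - 1:
                    uyp = u[i, j + 1, k]
                    hyp = yc[j + 1] - yc[j]
                else:
                    uyp = u0
                    hyp = dy[ny - 1]
                if k > 0:
                    uzm = u[i, j, k - 1]
                    hzm = zc[k] - zc[k - 1]
                else:
                    uzm = u0
                    hzm = dz[0]
                if k < nz - 1:
                    uzp = u[i, j, k + 1]
                    hzp = zc[k + 1] - zc[k]
                else:
                    uzp = u0
                    hzp = dz[nz - 1]
                vb = 0.25 * (v[im, j, k] + v[im, j + 1, k] + v[i, j, k] + v[i, j + 1, k])
                wb = 0.25 * (w[im, j, k] + w[im, j, k + 1] + w[i, j, k] + w[i, j, k + 1])
                adv = (
                    _hybrid(u0, uxm, uxp, dx, dx, u0, nu, central)
                    + _hybrid(u0, uym, uyp, hym, hyp, vb, nu, central and j < j_outlet_upwind)
                    + _hybrid(u0, uzm, uzp, hzm, hzp, wb, nu, central)
                )
                lap = (
                    (uxp - 2.0 * u0 + uxm) / (dx * dx)
                    + _lap1(u0, uym, uyp, hym, hyp)
                    + _lap1(u0, uzm, uzp, hzm, hzp)
                )
                gp = (p[i, j, k] - p[im, j, k]) / dx
                rhs = -adv - gp / rho + nu * lap
                if dt_phys_inv > 0.0:
                    rhs -= (u0 - u_prev[i, j, k]) * dt_phys_inv
                if local_dt:
                    hy = hym if hym < hyp else hyp
                    hz = hzm if hzm < hzp else hzp
                    denom = (
                        (abs(u0) + c) / dx
                        + (abs(vb) + c) / hy
                        + (abs(wb) + c) / hz
                        + 2.0 * nu * (1.0 / (dx * dx) + 1.0 / (hy * hy) + 1.0 / (hz * hz))
                        + dt_phys_inv
                    )
                    if central:
                        denom += (u0 * u0 + vb * vb + wb * wb) / (2.0 * nu)
                    dt = cfl / denom
                else:
                    dt = dt_fixed
                un[i, j, k] = u0 + dt * rhs
                res_sq += rhs * rhs
                if abs(rhs) > res_max:
                    res_max = abs(rhs)
                nfaces += 1

    # ----- v (y-faces), j = 1 .. ny (j=0 is the fixed inlet) -----
    for i in range(nx):
        ip = i + 1 if i < nx - 1 else 0
        im = i - 1 if i > 0 else nx - 1
        for j in range(1, ny + 1):
            for k in range(nz):
                if solid_v[i, j, k]:
                    vn[i, j, k] = 0.0
                    continue
                v0 = v[i, j, k]
                vxm = v[im, j, k]
                vxp = v[ip, j, k]
                vym = v[i, j - 1, k]
                hym = dy[j - 1]
                if j < ny:
                    vyp = v[i, j + 1, k]
                    hyp = dy[j]
                else:
                    vyp = v0
                    hyp = dy[ny - 1]
                if k > 0:
                    vzm = v[i, j, k - 1]
                    hzm = zc[k] - zc[k - 1]
                else:
                    vzm = v0
                    hzm = dz[0]
                if k < nz - 1:
                    vzp = v[i, j, k + 1]
                    hzp = zc[k + 1] - zc[k]
                else:
                    vzp = v0
                    hzp = dz[nz - 1]
                if j < ny:
                    ub = 0.25 * (u[i, j - 1, k] + u[ip, j - 1, k] + u[i, j, k] + u[ip, j, k])
                    wb = 0.25 * (w[i, j - 1, k] + w[i, j - 1, k + 1] + w[i, j, k] + w[i, j, k + 1])
                else:
                    ub = 0.5 * (u[i, ny - 1, k] + u[ip, ny - 1, k])
                    wb = 0.5 * (w[i, ny - 1, k] + w[i, ny - 1, k + 1])
                adv = (
                    _hybrid(v0, vxm, vxp, dx, dx, ub, nu, central)
                    + _hybrid(v0, vym, vyp, hym, hyp, v0, nu, central and j < j_outlet_upwind)
                    + _hybrid(v0, vzm, vzp, hzm, hzp, wb, nu, central)
                )
                lap = (
                    (vxp - 2.0 * v0 + vxm) / (dx * dx)
                    + _lap1(v0, vym, vyp, hym, hyp)
                    + _lap1(v0, vzm, vzp, hzm, hzp)
                )
                if j < ny:
                    gp = (p[i, j, k] - p[i, j - 1, k]) / (yc[j] - yc[j - 1])
                else:
                    # zero-pressure outlet face: ghost cell mirrors -p
                    gp = (0.0 - p[i, ny - 1, k]) * 2.0 / dy[ny - 1]
                rhs = -adv - gp / rho + nu * lap
                if dt_phys_inv > 0.0:
                    rhs -= (v0 - v_prev[i, j, k]) * dt_phys_inv
                if local_dt:
                    hy = hym if hym < hyp else hyp
                    hz = hzm if hzm < hzp else hzp
                    denom = (
                        (abs(ub) + c) / dx
                        + (abs(v0) + c) / hy
                        + (abs(wb) + c) / hz
                        + 2.0 * nu * (1.0 / (dx * dx) + 1.0 / (hy * hy) + 1.0 / (hz * hz))
                        + dt_phys_inv
                    )
                    if central:
                        denom += (ub * ub + v0 * v0 + wb * wb) / (2.0 * nu)
                    dt = cfl / denom
                else:
                    dt = dt_fixed
                vn[i, j, k] = v0 + dt * rhs
                res_sq += rhs * rhs
                if abs(rhs) > res_max:
                    res_max = abs(rhs)
                nfaces += 1
        for k in range(nz):
            vn[i, 0, k] = u_inlet

    # ----- w (z-faces), k = 1 .. nz-1 (k=0 and nz are free-slip, w=0) -----
    for i in range(nx):
        ip = i + 1 if i < nx - 1 else 0
        im = i - 1 if i > 0 else nx - 1
        for j in range(ny):
            for k in range(1, nz):
                if solid_w[i, j, k]:
                    wn[i, j, k] = 0.0
                    continue
                w0 = w[i, j, k]
                wxm = w[im, j, k]
                wxp = w[ip, j, k]
                if j > 0:
                    wym = w[i, j - 1, k]
                    hym = yc[j] - yc[j - 1]
                else:
                    wym = -w0
                    hym = 2.0 * yc[0]
                if j < ny - 1:
                    wyp = w[i, j + 1, k]
                    hyp = yc[j + 1] - yc[j]
                else:
                    wyp = w0
                    hyp = dy[ny - 1]
                wzm = w[i, j, k - 1]
                wzp = w[i, j, k + 1]
                hzm = dz[k - 1]
                hzp = dz[k] if k < nz else dz[nz - 1]
                ub = 0.25 * (u[i, j, k - 1] + u[ip, j, k - 1] + u[i, j, k] + u[ip, j, k])
                vb = 0.25 * (v[i, j, k - 1] + v[i, j + 1, k - 1] + v[i, j, k] + v[i, j + 1, k])
                adv = (
                    _hybrid(w0, wxm, wxp, dx, dx, ub, nu, central)
                    + _hybrid(w0, wym, wyp, hym, hyp, vb, nu, central and j < j_outlet_upwind)
                    + _hybrid(w0, wzm, wzp, hzm, hzp, w0, nu, central)
                )
                lap = (
                    (wxp - 2.0 * w0 + wxm) / (dx * dx)
                    + _lap1(w0, wym, wyp, hym, hyp)
                    + _lap1(w0, wzm, wzp, hzm, hzp)
                )
                gp = (p[i, j, k] - p[i, j, k - 1]) / (zc[k] - zc[k - 1])
                rhs = -adv - gp / rho + nu * lap
                if dt_phys_inv > 0.0:
                    rhs -= (w0 - w_prev[i, j, k]) * dt_phys_inv
                if local_dt:
                    hy = hym if hym < hyp else hyp
                    hz = hzm if hzm < hzp else hzp
                    denom = (
                        (abs(ub) + c) / dx
                        + (abs(vb) + c) / hy
                        + (abs(w0) + c) / hz
                        + 2.0 * nu * (1.0 / (dx * dx) + 1.0 / (hy * hy) + 1.0 / (hz * hz))
                        + dt_phys_inv
                    )
                    if central:
                        denom += (ub * ub + vb * vb + w0 * w0) / (2.0 * nu)
                    dt = cfl / denom
                else:
                    dt = dt_fixed
                wn[i, j, k] = w0 + dt * rhs
                res_sq += rhs * rhs
                if abs(rhs) > res_max:
                    res_max = abs(rhs)
                nfaces += 1
            wn[i, j, 0] = 0.0
            wn[i, j, nz] = 0.0

    return res_sq, res_max, nfaces


@njit(cache=True, fastmath=True)
def pressure_sweep(
    u, v, w, p,
    solid_p,
    dx, dy, dz,
    rho, beta,
    cfl, local_dt, dt_fixed,
):
    """Relax the pressure from the divergence of the (new) velocity field.

    Returns the maximum cell divergence scaled by the smallest cell extent
    (units of velocity), for the relative-divergence convergence check.
    """
    nx, ny, nz = p.shape
    c = np.sqrt(beta)
    div_scaled_max = 0.0
    for i in range(nx):
        ip = i + 1 if i < nx - 1 else 0
        for j in range(ny):
            for k in range(nz):
                if solid_p[i, j, k]:
                    continue
                div = (
                    (u[ip, j, k] - u[i, j, k]) / dx
                    + (v[i, j + 1, k] - v[i, j, k]) / dy[j]
                    + (w[i, j, k + 1] - w[i, j, k]) / dz[k]
                )
                hmin = dx
                if dy[j] < hmin:
                    hmin = dy[j]
                if dz[k] < hmin:
                    hmin = dz[k]
                ds = abs(div) * hmin
                if ds > div_scaled_max:
                    div_scaled_max = ds
                if local_dt:
                    ucc = 0.5 * abs(u[ip, j, k] + u[i, j, k])
                    vcc = 0.5 * abs(v[i, j + 1, k] + v[i, j, k])
                    wcc = 0.5 * abs(w[i, j, k + 1] + w[i, j, k])
                    denom = (
                        (ucc + c) / dx + (vcc + c) / dy[j] + (wcc + c) / dz[k]
                    )
                    dt = cfl / denom
                else:
                    dt = dt_fixed
                p[i, j, k] -= dt * rho * beta * div
    return div_scaled_max


@njit(cache=True, fastmath=True)
def section_fluxes(v, dx, dz):
    """Volumetric flux through every y-face plane (cm^3 s^-1)."""
    nx, nyp1, nz = v.shape
    out = np.zeros(nyp1)
    for j in range(nyp1):
        s = 0.0
        for i in range(nx):
            for k in range(nz):
                s += v[i, j, k] * dx * dz[k]
        out[j] = s
    return out


# ---------------------------------------------------------------------------
# interpolation
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _axis_index(coords, q):
    """Index/fraction for linear interpolation with edge clamping."""
    n = coords.shape[0]
    if q <= coords[0]:
        return 0, 0.0
    if q >= coords[n - 1]:
        return n - 2, 1.0
    idx = np.searchsorted(coords, q) - 1
    t = (q - coords[idx]) / (coords[idx + 1] - coords[idx])
    return idx, t


@njit(cache=True, fastmath=True)
def interp_velocity(xc, yc, zc, vel, period, px, py, pz):
    """Trilinear velocity interpolation; periodic in x when period > 0."""
    nx = xc.shape[0]
    if period > 0.0:
        xw = px % period
        dxg = period / nx  # uniform x spacing
        fi = (xw - xc[0]) / dxg
        i0 = int(np.floor(fi))
        tx = fi - i0
        ix0 = i0 % nx
        ix1 = (i0 + 1) % nx
    else:
        ix0, tx = _axis_index(xc, px)
        ix1 = ix0 + 1
    iy, ty = _axis_index(yc, py)
    iz, tz = _axis_index(zc, pz)
    out = np.zeros(3)
    for comp in range(3):
        c00 = vel[ix0, iy, iz, comp] * (1 - tx) + vel[ix1, iy, iz, comp] * tx
        c10 = vel[ix0, iy + 1, iz, comp] * (1 - tx) + vel[ix1, iy + 1, iz, comp] * tx
        c01 = vel[ix0, iy, iz + 1, comp] * (1 - tx) + vel[ix1, iy, iz + 1, comp] * tx
        c11 = vel[ix0, iy + 1, iz + 1, comp] * (1 - tx) + vel[ix1, iy + 1, iz + 1, comp] * tx
        c0 = c00 * (1 - ty) + c10 * ty
        c1 = c01 * (1 - ty) + c11 * ty
        out[comp] = c0 * (1 - tz) + c1 * tz
    return out


@njit(cache=True, fastmath=True)
def interp_many(xc, yc, zc, vel, period, pts):
    """Trilinear interpolation of a vector field at many points."""
    n = pts.shape[0]
    out = np.empty((n, 3))
    for i in range(n):
        out[i] = interp_velocity(xc, yc, zc, vel, period, pts[i, 0], pts[i, 1], pts[i, 2])
    return out


# ---------------------------------------------------------------------------
# agent transport
# ---------------------------------------------------------------------------

STATUS_ACTIVE = 0
STATUS_CAPTURED = 1
STATUS_EXITED = 2


@njit(cache=True, inline="always")
def _segment_hits_cylinder(x0, y0, z0, x1, y1, z1, cx, cy, r, zlo, zhi):
    """Earliest parameter t in [0,1] where the segment touches the finite
    cylinder (side or flat caps); returns -1.0 for no contact."""
    ax = x0 - cx
    ay = y0 - cy
    dxs = x1 - x0
    dys = y1 - y0
    dzs = z1 - z0
    # already inside at start?
    if ax * ax + ay * ay <= r * r and zlo <= z0 <= zhi:
        return 0.0
    t_best = -1.0
    # side surface
    aq = dxs * dxs + dys * dys
    bq = 2.0 * (ax * dxs + ay * dys)
    cq = ax * ax + ay * ay - r * r
    if aq > 0.0:
        disc = bq * bq - 4.0 * aq * cq
        if disc >= 0.0:
            sq = np.sqrt(disc)
            for t in ((-bq - sq) / (2.0 * aq), (-bq + sq) / (2.0 * aq)):
                if 0.0 <= t <= 1.0:
                    zt = z0 + t * dzs
                    if zlo <= zt <= zhi:
                        if t_best < 0.0 or t < t_best:
                            t_best = t
    # flat caps
    if dzs != 0.0:
        for zcap in (zlo, zhi):
            t = (zcap - z0) / dzs
            if 0.0 <= t <= 1.0:
                xt = x0 + t * dxs - cx
                yt = y0 + t * dys - cy
                if xt * xt + yt * yt <= r * r:
                    if t_best < 0.0 or t < t_best:
                        t_best = t
    return t_best


@njit(cache=True, fastmath=True)
def advance_agents(
    pos, status,
    xc, yc, zc, vel, period,
    normals, dt, sig,
    ly, lz,
    axis_x0, cell_width, radius, axis_y, cyl_z0, cyl_z1,
    y_retire,
):
    """Advance agents over one chunk of Euler-Maruyama steps.

    ``normals`` has shape (n_steps, n_agents, 3).  Captured/exited agents are
    frozen.  Agents beyond ``y_retire`` (where advection makes return to the
    cylinders impossible) are marked exited early; pass a value > ly to
    disable.  Returns the number of still-active agents.
    """
    nsteps = normals.shape[0]
    n = pos.shape[0]
    n_active = 0
    for a in range(n):
        if status[a] != STATUS_ACTIVE:
            continue
        x = pos[a, 0]
        y = pos[a, 1]
        z = pos[a, 2]
        for s in range(nsteps):
            uvec = interp_velocity(xc, yc, zc, vel, period, x, y, z)
            x1 = x + uvec[0] * dt + sig * normals[s, a, 0]
            y1 = y + uvec[1] * dt + sig * normals[s, a, 1]
            z1 = z + uvec[2] * dt + sig * normals[s, a, 2]
            # capture test against the nearest cylinder images (unwrapped x);
            # radius <= 0 disables obstacles (analytic-fixture transport)
            hit_t = -1.0
            if radius > 0.0:
                xmid = 0.5 * (x + x1)
                m = np.floor((xmid - axis_x0) / cell_width + 0.5)
                for dm in (-1.0, 0.0, 1.0):
                    cx = axis_x0 + (m + dm) * cell_width
                    t = _segment_hits_cylinder(
                        x, y, z, x1, y1, z1, cx, axis_y, radius, cyl_z0, cyl_z1
                    )
                    if t >= 0.0 and (hit_t < 0.0 or t < hit_t):
                        hit_t = t
            if hit_t >= 0.0:
                status[a] = STATUS_CAPTURED
                x = x + hit_t * (x1 - x)
                y = y + hit_t * (y1 - y)
                z = z + hit_t * (z1 - z)
                break
            # boundary handling: periodic x, reflect at inlet plane and
            # top/bottom, exit through the outlet
            if 0.0 <= x1 < period:
                x = x1
            else:
                x = x1 % period
            y = y1
            z = z1
            if y < 0.0:
                y = -y
            if z < 0.0:
                z = -z
            elif z > lz:
                z = 2.0 * lz - z
            if y >= ly or y > y_retire:
                status[a] = STATUS_EXITED
                break
        pos[a, 0] = x
        pos[a, 1] = y
        pos[a, 2] = z
        if status[a] == STATUS_ACTIVE:
            n_active += 1
    return n_active
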