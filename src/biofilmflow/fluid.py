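"""Locally averaged incompressible Navier-Stokes on a staggered grid.

The carrier fluid satisfies the volume-fraction-weighted equations

    div( eps_s U_s + eps_f U_f ) = 0
    d(eps_f U_f)/dt + div(eps_f U_f U_f)
        = (1/rho_f) ( -grad p + eps_f div R + F_fp )

with eps_f = 1 - eps_s the local fluid fraction, U_s the cell-averaged
particle velocity and F_fp the particle-reaction force density.  Only the
viscous part of the stress R is kept (channel Reynolds numbers of order
1-15; no turbulence closure).

Discretisation: MAC staggering (velocities on faces, pressure at centers),
first-order upwind advection, explicit viscous diffusion, and a projection
step whose constant-coefficient Poisson equation is factorised once per
grid.  Driving modes: ``couette`` (moving top lid, cyclic x and y) and
``inlet`` (prescribed uniform inflow, zero-gradient outflow).  The bottom
wall is no-slip in both modes; y (spanwise) is always cyclic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .core import FluidProps

__all__ = [
    "BoundaryConditions",
    "FluidGrid",
    "step_fluid",
    "apply_boundary_conditions",
    "run_to_steady",
    "reynolds_number",
    "nominal_shear_rate",
]


@dataclass
class BoundaryConditions:
    """Driving boundary data: mode plus the instantaneous speed U (m/s).

    ``body_force`` (N/m3) imposes a uniform driving force, e.g. the
    constant pressure gradient of a plane Poiseuille flow.
    """

    mode: str = "couette"  # "couette" (moving lid) or "inlet"
    U: float = 0.0
    body_force: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.mode not in ("couette", "inlet"):
            raise ValueError(f"unknown driving mode {self.mode!r}")


class FluidGrid:
    """Eulerian state on an (nx, ny, nz) cell grid over a box of ``extent``.

    Face-centered velocities: ``u`` (nx+1, ny, nz), ``v`` (nx, ny+1, nz),
    ``w`` (nx, ny, nz+1) -- along cyclic axes the first and last face are
    the same physical face and are kept equal.  Cell-centered fields:
    ``p``, ``eps_s``, ``U_s`` (.., 3), ``F_fp`` (.., 3).
    """

    def __init__(self, shape, extent, props: FluidProps = FluidProps(),
                 mode: str = "couette"):
        self.nx, self.ny, self.nz = (int(s) for s in shape)
        self.extent = np.asarray(extent, float)
        self.h = self.extent / np.array([self.nx, self.ny, self.nz])
        self.props = props
        self.mode = mode
        self.periodic_x = mode == "couette"
        self.u = np.zeros((self.nx + 1, self.ny, self.nz))
        self.v = np.zeros((self.nx, self.ny + 1, self.nz))
        self.w = np.zeros((self.nx, self.ny, self.nz + 1))
        self.p = np.zeros((self.nx, self.ny, self.nz))
        self.eps_s = np.zeros((self.nx, self.ny, self.nz))
        self.U_s = np.zeros((self.nx, self.ny, self.nz, 3))
        self.F_fp = np.zeros((self.nx, self.ny, self.nz, 3))
        # semi-implicit drag sink: relaxation rate K (1/s) toward the
        # drag-weighted particle velocity Up (stiff cells would otherwise
        # force the fluid step far below the drag response time)
        self.drag_K = np.zeros((self.nx, self.ny, self.nz))
        self.drag_Up = np.zeros((self.nx, self.ny, self.nz, 3))
        self._poisson = None

    # -- derived fields ----------------------------------------------------
    @property
    def eps_f(self) -> np.ndarray:
        return 1.0 - self.eps_s

    def cell_volume(self) -> float:
        return float(np.prod(self.h))

    def cell_centers(self):
        return tuple((np.arange(n) + 0.5) * h
                     for n, h in zip((self.nx, self.ny, self.nz), self.h))

    def center_velocity(self) -> np.ndarray:
        """Cell-centered velocity (average of the bounding faces)."""
        uc = 0.5 * (self.u[:-1] + self.u[1:])
        vc = 0.5 * (self.v[:, :-1] + self.v[:, 1:])
        wc = 0.5 * (self.w[:, :, :-1] + self.w[:, :, 1:])
        return np.stack([uc, vc, wc], axis=-1)

    def max_speed(self) -> float:
        return max(float(np.abs(self.u).max()), float(np.abs(self.v).max()),
                   float(np.abs(self.w).max()))

    # -- continuity diagnostics --------------------------------------------
    def _face_eps(self):
        """eps_f averaged to u, v, w faces (cyclic wrap along x, y)."""
        ef = self.eps_f
        efu = np.empty_like(self.u)
        efu[1:-1] = 0.5 * (ef[:-1] + ef[1:])
        if self.periodic_x:
            efu[0] = efu[-1] = 0.5 * (ef[0] + ef[-1])
        else:
            efu[0], efu[-1] = ef[0], ef[-1]
        efv = np.empty_like(self.v)
        efv[:, 1:-1] = 0.5 * (ef[:, :-1] + ef[:, 1:])
        efv[:, 0] = efv[:, -1] = 0.5 * (ef[:, 0] + ef[:, -1])
        efw = np.zeros_like(self.w)
        efw[:, :, 1:-1] = 0.5 * (ef[:, :, :-1] + ef[:, :, 1:])
        efw[:, :, 0], efw[:, :, -1] = ef[:, :, 0], ef[:, :, -1]
        return efu, efv, efw

    def _solid_flux_divergence(self) -> np.ndarray:
        """div(eps_s U_s), cell-centered, by face averaging."""
        hx, hy, hz = self.h
        q = self.eps_s[..., None] * self.U_s
        qx, qy, qz = q[..., 0], q[..., 1], q[..., 2]
        if self.periodic_x:
            fx = 0.5 * (qx + np.roll(qx, 1, axis=0))  # flux at face i-1/2
            div = (np.roll(fx, -1, axis=0) - fx) / hx
        else:  # closed transverse flux at inlet/outlet boundary
            fx = np.zeros((self.nx + 1, self.ny, self.nz))
            fx[1:-1] = 0.5 * (qx[:-1] + qx[1:])
            div = (fx[1:] - fx[:-1]) / hx
        fy = 0.5 * (qy + np.roll(qy, 1, axis=1))
        div += (np.roll(fy, -1, axis=1) - fy) / hy
        fz = np.zeros((self.nx, self.ny, self.nz + 1))
        fz[:, :, 1:-1] = 0.5 * (qz[:, :, :-1] + qz[:, :, 1:])
        div += (fz[:, :, 1:] - fz[:, :, :-1]) / hz
        return div

    def mixture_divergence(self) -> np.ndarray:
        """Residual div(eps_f U_f + eps_s U_s) per cell (1/s)."""
        hx, hy, hz = self.h
        efu, efv, efw = self._face_eps()
        qu, qv, qw = efu * self.u, efv * self.v, efw * self.w
        div = ((qu[1:] - qu[:-1]) / hx + (qv[:, 1:] - qv[:, :-1]) / hy
               + (qw[:, :, 1:] - qw[:, :, :-1]) / hz)
        return div + self._solid_flux_divergence()

    def continuity_residual(self) -> float:
        """Max mixture-continuity residual, relative to the velocity scale."""
        scale = max(self.max_speed(), 1e-30) / float(self.h.min())
        return float(np.abs(self.mixture_divergence()).max()) / scale

    # -- Poisson operator (factorised once; geometry is fixed) -------------
    def _poisson_solver(self):
        if self._poisson is not None:
            return self._poisson
        nx, ny, nz = self.nx, self.ny, self.nz
        hx, hy, hz = self.h
        n = nx * ny * nz

        def idx(i, j, k):
            return (i % nx) * ny * nz + (j % ny) * nz + k

        rows, cols, vals = [], [], []
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    c = idx(i, j, k)
                    diag = 0.0
                    for di in (-1, 1):
                        ii = i + di
                        if self.periodic_x or 0 <= ii < nx:
                            rows.append(c); cols.append(idx(ii, j, k))
                            vals.append(1.0 / hx**2)
                            diag -= 1.0 / hx**2
                        elif ii == nx:  # outflow: Dirichlet phi = 0 outside
                            diag -= 2.0 / hx**2
                        # inlet ghost (ii == -1): Neumann, no contribution
                    for dj in (-1, 1):
                        rows.append(c); cols.append(idx(i, j + dj, k))
                        vals.append(1.0 / hy**2)
                        diag -= 1.0 / hy**2
                    for dk in (-1, 1):
                        if 0 <= k + dk < nz:
                            rows.append(c); cols.append(idx(i, j, k + dk))
                            vals.append(1.0 / hz**2)
                            diag -= 1.0 / hz**2
                        # z walls: Neumann
                    rows.append(c); cols.append(c); vals.append(diag)
        mat = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
        if self.periodic_x:
            # gauge-fix the constant nullspace by pinning cell 0
            mat = mat.tolil()
            mat[0, :] = 0.0
            mat[0, 0] = 1.0
            mat = mat.tocsr()
        self._poisson = spla.splu(mat.tocsc())
        return self._poisson


def reynolds_number(U: float, width: float, height: float,
                    props: FluidProps = FluidProps()) -> float:
    """Channel Reynolds number with the duct hydraulic diameter
    Dh = 4 A / P = 4 (W H) / (2 (W + H))."""
    if width <= 0 or height <= 0:
        raise ValueError("duct dimensions must be positive")
    dh = 4.0 * width * height / (2.0 * (width + height))
    return props.rho_f * U * dh / props.mu


def nominal_shear_rate(U: float, H: float) -> float:
    """Nominal shear rate U / H across the channel height."""
    if H <= 0:
        raise ValueError("channel height must be positive")
    return U / H


# -- boundary conditions ---------------------------------------------------

def apply_boundary_conditions(grid: FluidGrid, bc: BoundaryConditions) -> FluidGrid:
    """Enforce wall/inlet values on the face fields in place.

    The bottom wall is exactly no-slip; the top is the moving lid
    (couette, speed ``bc.U``) or free-slip (inlet); x is cyclic (couette)
    or prescribed-inflow / zero-gradient-outflow (inlet).  Wall-normal
    velocities vanish on both z walls.
    """
    if bc.mode != grid.mode:
        raise ValueError(f"bc mode {bc.mode!r} does not match grid {grid.mode!r}")
    grid.w[:, :, 0] = 0.0
    grid.w[:, :, -1] = 0.0
    if bc.mode == "couette":
        grid.u[0] = grid.u[-1] = 0.5 * (grid.u[0] + grid.u[-1])
        grid.v[:, 0] = grid.v[:, -1] = 0.5 * (grid.v[:, 0] + grid.v[:, -1])
    else:
        grid.u[0] = bc.U
        grid.u[-1] = grid.u[-2]
        grid.v[:, 0] = grid.v[:, -1] = 0.5 * (grid.v[:, 0] + grid.v[:, -1])
    return grid


# -- padding helpers: one ghost layer per axis -----------------------------

def _pad_axis_cell(f, axis, periodic):
    """Ghosts for an axis along which the field is cell-centered."""
    lo = [slice(None)] * 3
    hi = [slice(None)] * 3
    lo[axis] = slice(-1, None) if periodic else slice(0, 1)
    hi[axis] = slice(0, 1) if periodic else slice(-1, None)
    return np.concatenate([f[tuple(lo)], f, f[tuple(hi)]], axis=axis)


def _pad_axis_face_periodic(f, axis):
    """Ghosts for a cyclic axis along which the field is face-centered
    (first and last stored face coincide)."""
    lo = [slice(None)] * 3
    hi = [slice(None)] * 3
    lo[axis] = slice(-2, -1)
    hi[axis] = slice(1, 2)
    return np.concatenate([f[tuple(lo)], f, f[tuple(hi)]], axis=axis)


def _pad_z_wall(f, bottom, top, U_top=0.0):
    """z ghosts for a z-cell-centered field: 'noslip' (wall value 0),
    'lid' (wall value U_top) or 'slip' (zero gradient)."""
    def ghost(layer, kind):
        return {"noslip": -layer, "slip": layer, "lid": 2.0 * U_top - layer}[kind]
    return np.concatenate([ghost(f[:, :, :1], bottom), f,
                           ghost(f[:, :, -1:], top)], axis=2)


def _upwind(fp, a, axis, h):
    """First-order upwind a * df/dx_axis from a once-padded field."""
    ctr = [slice(1, -1)] * 3
    fwd, bwd = list(ctr), list(ctr)
    fwd[axis] = slice(2, None)
    bwd[axis] = slice(0, -2)
    df_b = (fp[tuple(ctr)] - fp[tuple(bwd)]) / h
    df_f = (fp[tuple(fwd)] - fp[tuple(ctr)]) / h
    return a * np.where(a > 0.0, df_b, df_f)


def _laplacian(fp, h):
    hx, hy, hz = h
    c = fp[1:-1, 1:-1, 1:-1]
    return ((fp[2:, 1:-1, 1:-1] - 2 * c + fp[:-2, 1:-1, 1:-1]) / hx**2
            + (fp[1:-1, 2:, 1:-1] - 2 * c + fp[1:-1, :-2, 1:-1]) / hy**2
            + (fp[1:-1, 1:-1, 2:] - 2 * c + fp[1:-1, 1:-1, :-2]) / hz**2)


def step_fluid(grid: FluidGrid, dt: float, bc: BoundaryConditions) -> FluidGrid:
    """Advance one projection step: advect + diffuse + force, then project
    onto the mixture-continuity constraint.

    Raises on a violated CFL / viscous stability bound or on a failed
    pressure solve.  After the step  div(eps_f U_f + eps_s U_s) = 0
    holds to direct-solver precision.
    """
    nu = grid.props.nu
    hx, hy, hz = grid.h
    umax = max(grid.max_speed(), abs(bc.U))
    cfl = umax * dt / float(grid.h.min())
    if cfl >= 0.5:
        raise ValueError(f"advective CFL {cfl:.2f} >= 0.5")
    visc = 2.0 * nu * dt * (1 / hx**2 + 1 / hy**2 + 1 / hz**2)
    if visc >= 1.0:
        raise ValueError(f"viscous stability number {visc:.2f} >= 1")

    apply_boundary_conditions(grid, bc)
    u, v, w = grid.u, grid.v, grid.w
    nx, ny, nz = grid.nx, grid.ny, grid.nz
    rho = grid.props.rho_f
    lid = bc.U if bc.mode == "couette" else 0.0
    top_u = "lid" if bc.mode == "couette" else "slip"
    top_v = "noslip" if bc.mode == "couette" else "slip"

    # padded fields; ghosts encode the boundary conditions
    up = _pad_z_wall(u, "noslip", top_u, lid)
    up = _pad_axis_cell(up, 1, True)
    up = (_pad_axis_face_periodic(up, 0) if grid.periodic_x
          else _pad_axis_cell(up, 0, False))
    vp = _pad_z_wall(v, "noslip", top_v)
    vp = _pad_axis_face_periodic(vp, 1)
    vp = _pad_axis_cell(vp, 0, grid.periodic_x)
    wp = np.concatenate([-w[:, :, 1:2], w, -w[:, :, -2:-1]], axis=2)
    wp = _pad_axis_cell(wp, 1, True)
    wp = _pad_axis_cell(wp, 0, grid.periodic_x)

    # cross velocities at each staggered location (padded-index slices)
    v_at_u = 0.25 * (vp[0:nx + 1, 1:ny + 1, 1:nz + 1]
                     + vp[0:nx + 1, 2:ny + 2, 1:nz + 1]
                     + vp[1:nx + 2, 1:ny + 1, 1:nz + 1]
                     + vp[1:nx + 2, 2:ny + 2, 1:nz + 1])
    w_at_u = 0.25 * (wp[0:nx + 1, 1:ny + 1, 1:nz + 1]
                     + wp[0:nx + 1, 1:ny + 1, 2:nz + 2]
                     + wp[1:nx + 2, 1:ny + 1, 1:nz + 1]
                     + wp[1:nx + 2, 1:ny + 1, 2:nz + 2])
    u_at_v = 0.25 * (up[1:nx + 1, 0:ny + 1, 1:nz + 1]
                     + up[2:nx + 2, 0:ny + 1, 1:nz + 1]
                     + up[1:nx + 1, 1:ny + 2, 1:nz + 1]
                     + up[2:nx + 2, 1:ny + 2, 1:nz + 1])
    w_at_v = 0.25 * (wp[1:nx + 1, 0:ny + 1, 1:nz + 1]
                     + wp[1:nx + 1, 0:ny + 1, 2:nz + 2]
                     + wp[1:nx + 1, 1:ny + 2, 1:nz + 1]
                     + wp[1:nx + 1, 1:ny + 2, 2:nz + 2])
    u_at_w = 0.25 * (up[1:nx + 1, 1:ny + 1, 0:nz + 1]
                     + up[2:nx + 2, 1:ny + 1, 0:nz + 1]
                     + up[1:nx + 1, 1:ny + 1, 1:nz + 2]
                     + up[2:nx + 2, 1:ny + 1, 1:nz + 2])
    v_at_w = 0.25 * (vp[1:nx + 1, 1:ny + 1, 0:nz + 1]
                     + vp[1:nx + 1, 2:ny + 2, 0:nz + 1]
                     + vp[1:nx + 1, 1:ny + 1, 1:nz + 2]
                     + vp[1:nx + 1, 2:ny + 2, 1:nz + 2])

    adv_u = (_upwind(up, u, 0, hx) + _upwind(up, v_at_u, 1, hy)
             + _upwind(up, w_at_u, 2, hz))
    adv_v = (_upwind(vp, u_at_v, 0, hx) + _upwind(vp, v, 1, hy)
             + _upwind(vp, w_at_v, 2, hz))
    adv_w = (_upwind(wp, u_at_w, 0, hx) + _upwind(wp, v_at_w, 1, hy)
             + _upwind(wp, w, 2, hz))

    lap_u, lap_v, lap_w = (_laplacian(fp, grid.h) for fp in (up, vp, wp))

    # fluid-particle reaction + body force per unit fluid mass, at faces
    ef_safe = np.maximum(grid.eps_f, 0.3)  # bounded below dense packing

    def face_x(c):
        if grid.periodic_x:
            f = 0.5 * (c + np.roll(c, 1, axis=0))
            return np.concatenate([f, f[:1]], axis=0)
        out = np.zeros((nx + 1,) + c.shape[1:])
        out[1:-1] = 0.5 * (c[:-1] + c[1:])
        out[0], out[-1] = c[0], c[-1]
        return out

    def face_y(c):
        f = 0.5 * (c + np.roll(c, 1, axis=1))
        return np.concatenate([f, f[:, :1]], axis=1)

    def face_z(c):
        out = np.zeros(c.shape[:2] + (c.shape[2] + 1,))
        out[:, :, 1:-1] = 0.5 * (c[:, :, :-1] + c[:, :, 1:])
        return out

    gx, gy, gz = bc.body_force
    acc = grid.F_fp / (rho * ef_safe[..., None])
    fu = face_x(acc[..., 0] + gx / rho)
    fv = face_y(acc[..., 1] + gy / rho)
    fw = face_z(acc[..., 2] + gz / rho)

    grid.u = u + dt * (-adv_u + nu * lap_u + fu)
    grid.v = v + dt * (-adv_v + nu * lap_v + fv)
    grid.w = w + dt * (-adv_w + nu * lap_w + fw)

    if np.any(grid.drag_K > 0.0):
        # implicit drag sink: u <- (u + dt K Up) / (1 + dt K), face-wise
        ku = face_x(grid.drag_K)
        kv = face_y(grid.drag_K)
        kw = face_z(grid.drag_K)
        grid.u = (grid.u + dt * ku * face_x(grid.drag_Up[..., 0])) \
            / (1.0 + dt * ku)
        grid.v = (grid.v + dt * kv * face_y(grid.drag_Up[..., 1])) \
            / (1.0 + dt * kv)
        grid.w = (grid.w + dt * kw * face_z(grid.drag_Up[..., 2])) \
            / (1.0 + dt * kw)
    apply_boundary_conditions(grid, bc)

    # --- projection: div(eps_f u) = -div(eps_s U_s) ---
    efu, efv, efw = grid._face_eps()
    qu, qv, qw = efu * grid.u, efv * grid.v, efw * grid.w
    div = ((qu[1:] - qu[:-1]) / hx + (qv[:, 1:] - qv[:, :-1]) / hy
           + (qw[:, :, 1:] - qw[:, :, :-1]) / hz)
    rhs = (rho / dt) * (div + grid._solid_flux_divergence())
    b = rhs.ravel().copy()
    if grid.periodic_x:
        b -= b.mean()  # compatibility for the gauge-fixed Neumann problem
        b[0] = 0.0
    phi = grid._poisson_solver().solve(b)
    if not np.all(np.isfinite(phi)):
        raise RuntimeError("pressure solve failed: non-finite solution")
    phi = phi.reshape(grid.p.shape)
    grid.p = phi

    scale = dt / rho
    if grid.periodic_x:
        dphix = (phi - np.roll(phi, 1, axis=0)) / hx  # at face i-1/2
        gradu = np.concatenate([dphix, dphix[:1]], axis=0)
    else:
        gradu = np.zeros_like(grid.u)
        gradu[1:-1] = (phi[1:] - phi[:-1]) / hx
        gradu[-1] = (0.0 - phi[-1]) / (0.5 * hx)  # Dirichlet 0 at outlet face
    dphiy = (phi - np.roll(phi, 1, axis=1)) / hy
    gradv = np.concatenate([dphiy, dphiy[:, :1]], axis=1)
    gradw = np.zeros_like(grid.w)
    gradw[:, :, 1:-1] = (phi[:, :, 1:] - phi[:, :, :-1]) / hz

    grid.u -= scale * gradu / np.maximum(efu, 1e-12)
    grid.v -= scale * gradv / np.maximum(efv, 1e-12)
    grid.w -= scale * gradw / np.maximum(efw, 1e-12)
    apply_boundary_conditions(grid, bc)
    if bc.mode == "inlet":
        grid.u[0] = bc.U  # inflow is prescribed, never corrected
    return grid


def run_to_steady(grid: FluidGrid, bc: BoundaryConditions, dt: float,
                  tol: float = 1e-7, max_steps: int = 200000) -> FluidGrid:
    """Iterate :func:`step_fluid` to steady state.

    Stops when the velocity change rate max|du|/dt drops below
    ``tol * U_scale / t_visc`` with t_visc = H^2 / nu, i.e. the transient
    has decayed to a fraction ``tol`` of the initial evolution rate.
    """
    H = float(grid.extent[2])
    u_scale = max(abs(bc.U),
                  abs(bc.body_force[0]) * H**2 / (8.0 * grid.props.mu), 1e-30)
    rate_floor = tol * u_scale * grid.props.nu / H**2
    for _ in range(max_steps):
        prev = grid.u.copy()
        step_fluid(grid, dt, bc)
        if np.abs(grid.u - prev).max() / dt < rate_floor:
            break
    return grid
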