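"""Lagrangian mechanics of the agents (discrete element method).

Each bacterium / EPS agent obeys  m_i dv_i/dt = f_contact + f_cohesion +
f_fluid-particle.  Contacts are Hookean spring-dashpots (normal spring
k_n * overlap, overlap-scaled dashpots gamma * m_eff * overlap * v_rel,
tangential spring with per-contact history); cohesion is the sphere-sphere
Hamaker attraction

    |F| = (A/6) * 64 ri^3 rj^3 (s + ri + rj)
          / [(s^2 + 2 ri s + 2 rj s)^2 (s^2 + 2 ri s + 2 rj s + 4 ri rj)^2]

with the surface separation s clamped at s_min when particles touch.
For equal spheres at close approach this reduces to A r / (12 s^2).

The public API operates on :class:`~biofilmflow.core.Particle` pairs and
:class:`~biofilmflow.core.ParticleSystem`; the hot loop used by the flow
protocols is a numba kernel over flat pair arrays (one force evaluation
per velocity-Verlet step, wall particles pinned, cyclic x/y wrap).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

from .core import (ContactParams, CohesionMatrix, Particle, ParticleSystem,
                   ParticleType)

__all__ = [
    "PairForce",
    "contact_force",
    "cohesive_force",
    "cohesive_magnitude",
    "build_neighbor_list",
    "step_dem",
    "stability_dt",
    "NeighborState",
]


@dataclass(frozen=True)
class PairForce:
    """Force on particle i from particle j, with the branch vector i->j."""

    i: int
    j: int
    f_on_i: np.ndarray
    branch: np.ndarray

    @property
    def f_on_j(self) -> np.ndarray:
        return -self.f_on_i


def _branch(pi: Particle, pj: Particle) -> np.ndarray:
    return pj.position - pi.position


def contact_force(pi: Particle, pj: Particle, cp: ContactParams) -> PairForce:
    """Spring-dashpot contact force on ``pi`` (zero without surface overlap).

    Single-evaluation form: the tangential spring needs per-contact history
    and therefore contributes only its dashpot term here; the history term
    lives in the integration kernel.
    """
    branch = _branch(pi, pj)
    dist = float(np.linalg.norm(branch))
    if dist == 0.0:
        raise ValueError("coincident particle centers: contact normal undefined")
    nij = branch / dist
    delta = (pi.radius + pj.radius) - dist  # overlap > 0 means contact
    if delta <= 0.0:
        return PairForce(pi.id, pj.id, np.zeros(3), branch)
    m_eff = pi.mass * pj.mass / (pi.mass + pj.mass)
    v_rel = pi.velocity - pj.velocity
    vn = float(v_rel @ nij)
    vt = v_rel - vn * nij
    f = (-cp.k_n * delta * nij
         - cp.gamma_n * m_eff * delta * vn * nij
         - cp.gamma_t * m_eff * delta * vt)
    return PairForce(pi.id, pj.id, f, branch)


def cohesive_magnitude(s: float, ri: float, rj: float, A: float,
                       s_min: float) -> float:
    """Attractive Hamaker sphere-sphere force magnitude at separation s."""
    s = max(s, s_min)
    q = s * s + 2.0 * ri * s + 2.0 * rj * s
    num = 64.0 * ri**3 * rj**3 * (s + ri + rj)
    den = q * q * (q + 4.0 * ri * rj) ** 2
    return (A / 6.0) * num / den


def cohesive_force(pi: Particle, pj: Particle, A: float,
                   s_min: float = 1.0e-9) -> PairForce:
    """Hamaker attraction on ``pi`` directed toward ``pj``."""
    if A < 0:
        raise ValueError("cohesive strength A must be non-negative")
    branch = _branch(pi, pj)
    dist = float(np.linalg.norm(branch))
    if dist == 0.0:
        raise ValueError("coincident particle centers: cohesion normal undefined")
    nij = branch / dist
    s = dist - pi.radius - pj.radius
    mag = cohesive_magnitude(s, pi.radius, pj.radius, A, s_min)
    return PairForce(pi.id, pj.id, mag * nij, branch)


# -- neighbor search -------------------------------------------------------

def build_neighbor_list(system: ParticleSystem, cutoff: float,
                        exclude_wall_wall: bool = False) -> np.ndarray:
    """All unordered index pairs with surface gap < ``cutoff``.

    A pair qualifies when center distance < cutoff + ri + rj, honoring the
    cyclic x/y axes (minimum image).  Returns an (M, 2) int array with
    i < j, lexicographically sorted.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    box = system.domain
    for ax in range(3):
        if system.periodic_axes[ax] and cutoff > 0.5 * box[ax]:
            raise ValueError("cutoff exceeds half the periodic box")
    n = system.n
    if n < 2:
        return np.empty((0, 2), dtype=np.int64)
    rmax = float(system.radius.max())
    search = cutoff + 2.0 * rmax
    # cKDTree periodic boxes wrap every axis; make non-periodic axes huge.
    boxsize = [box[ax] if system.periodic_axes[ax] else 1e9 for ax in range(3)]
    pts = system.pos.copy()
    for ax in range(3):
        if system.periodic_axes[ax]:
            pts[:, ax] %= box[ax]
    pts = np.clip(pts, 0.0, None)
    tree = cKDTree(pts, boxsize=boxsize)
    pairs = tree.query_pairs(search, output_type="ndarray")
    if len(pairs) == 0:
        return np.empty((0, 2), dtype=np.int64)
    d = pts[pairs[:, 0]] - pts[pairs[:, 1]]
    for ax in range(3):
        if system.periodic_axes[ax]:
            d[:, ax] -= box[ax] * np.round(d[:, ax] / box[ax])
    dist = np.linalg.norm(d, axis=1)
    keep = dist < cutoff + system.radius[pairs[:, 0]] + system.radius[pairs[:, 1]]
    if exclude_wall_wall:
        wall = int(ParticleType.WALL)
        keep &= ~((system.types[pairs[:, 0]] == wall)
                  & (system.types[pairs[:, 1]] == wall))
    pairs = pairs[keep]
    pairs.sort(axis=1)
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    return pairs[order].astype(np.int64)


class NeighborState:
    """Pair list plus per-contact tangential shear history.

    Rebuilding the list carries history over by matching pair keys, so a
    tangential spring survives list refreshes and is cleared only when the
    contact actually separates.
    """

    def __init__(self, system: ParticleSystem, cutoff: float,
                 pair_cutoff_factor: float | None = None,
                 skin: float = 0.0):
        self.cutoff = float(cutoff)
        # optional radius-aware trim: keep a pair only within its own
        # cohesion range (factor * min radius) plus the skin
        self.pair_cutoff_factor = pair_cutoff_factor
        self.skin = float(skin)
        self._wall_tree = None
        self._wall_idx = None
        self._n = system.n
        self.pairs = self._build(system)
        self.shear = np.zeros((len(self.pairs), 3))

    def _boxsize(self, system):
        return [system.domain[ax] if system.periodic_axes[ax] else 1e9
                for ax in range(3)]

    def _build(self, system: ParticleSystem) -> np.ndarray:
        """Fast pair search: mobile-mobile via a small tree, mobile-wall
        against a cached static wall tree (walls never move)."""
        box = system.domain
        for ax in range(3):
            if system.periodic_axes[ax] and self.cutoff > 0.5 * box[ax]:
                raise ValueError("cutoff exceeds half the periodic box")
        wall = system.types == int(ParticleType.WALL)
        pts = system.pos.copy()
        for ax in range(3):
            if system.periodic_axes[ax]:
                pts[:, ax] %= box[ax]
        pts = np.clip(pts, 0.0, None)
        boxsize = self._boxsize(system)
        if self._wall_tree is None and wall.any():
            self._wall_idx = np.where(wall)[0]
            self._wall_tree = cKDTree(pts[wall], boxsize=boxsize)
        mob_idx = np.where(~wall)[0]
        rmax = float(system.radius.max()) if system.n else 0.0
        search = self.cutoff + 2.0 * rmax
        chunks = []
        if len(mob_idx) >= 2:
            mtree = cKDTree(pts[mob_idx], boxsize=boxsize)
            mm = mtree.query_pairs(search, output_type="ndarray")
            if len(mm):
                chunks.append(mob_idx[mm])
            if self._wall_tree is not None:
                # walls live at z ~ 0: only near-wall mobiles can pair
                zmax = system.pos[self._wall_idx, 2].max() \
                    + system.radius[self._wall_idx].max()
                near = np.where(pts[mob_idx, 2] < zmax + search)[0]
                if len(near):
                    hits = self._wall_tree.query_ball_point(
                        pts[mob_idx[near]], search)
                    mw = [(mob_idx[near[a]], self._wall_idx[b])
                          for a, lst in enumerate(hits) for b in lst]
                    if mw:
                        chunks.append(np.array(mw, dtype=np.int64))
        elif len(mob_idx) == 1 and self._wall_tree is not None:
            lst = self._wall_tree.query_ball_point(pts[mob_idx[0]], search)
            if lst:
                chunks.append(np.array([(mob_idx[0], self._wall_idx[b])
                                        for b in lst], dtype=np.int64))
        if not chunks:
            return np.empty((0, 2), dtype=np.int64)
        pairs = np.vstack(chunks)
        d = pts[pairs[:, 0]] - pts[pairs[:, 1]]
        for ax in range(3):
            if system.periodic_axes[ax]:
                d[:, ax] -= box[ax] * np.round(d[:, ax] / box[ax])
        dist = np.linalg.norm(d, axis=1)
        ri = system.radius[pairs[:, 0]]
        rj = system.radius[pairs[:, 1]]
        if self.pair_cutoff_factor is not None:
            keep = dist < (self.pair_cutoff_factor * np.minimum(ri, rj)
                           + self.skin + ri + rj)
        else:
            keep = dist < self.cutoff + ri + rj
        pairs = pairs[keep]
        pairs.sort(axis=1)
        order = np.lexsort((pairs[:, 1], pairs[:, 0]))
        return np.ascontiguousarray(pairs[order])

    def _keys(self, pairs: np.ndarray) -> np.ndarray:
        return pairs[:, 0] * np.int64(self._n) + pairs[:, 1]

    def invalidate_walls(self) -> None:
        """Forget the cached wall tree (after particle deletion)."""
        self._wall_tree = None
        self._wall_idx = None

    def rebuild(self, system: ParticleSystem) -> None:
        old_pairs, old_shear = self.pairs, self.shear
        same_indexing = system.n == self._n
        if not same_indexing:  # deletion reindexed the particle arrays
            self.invalidate_walls()
            old_pairs = old_pairs[:0]
            old_shear = old_shear[:0]
        self._n = system.n
        self.pairs = self._build(system)
        self.shear = np.zeros((len(self.pairs), 3))
        if len(old_pairs) and len(self.pairs):
            old_keys = old_pairs[:, 0] * np.int64(self._n) + old_pairs[:, 1]
            new_keys = self._keys(self.pairs)
            idx = np.searchsorted(old_keys, new_keys)
            idx = np.clip(idx, 0, len(old_keys) - 1)
            hit = old_keys[idx] == new_keys
            self.shear[hit] = old_shear[idx[hit]]


# -- force/integration kernels --------------------------------------------

@njit(cache=True)
def _min_image(dx, dy, box0, box1, perx, pery):
    if perx:
        dx -= box0 * round(dx / box0)
    if pery:
        dy -= box1 * round(dy / box1)
    return dx, dy


def build_pair_data(system: ParticleSystem, pairs: np.ndarray,
                    cohesion: CohesionMatrix | None,
                    cutoff_factor: float) -> np.ndarray:
    """Per-pair constants consumed by the force kernel.

    Columns: cohesion prefactor (A/6)*64*ri^3*rj^3, 4*ri*rj, squared
    center-distance cutoff (gap = cutoff_factor * min radius), ri + rj,
    and the reduced mass.
    """
    out = np.zeros((len(pairs), 5))
    if len(pairs) == 0:
        return out
    i, j = pairs[:, 0], pairs[:, 1]
    ri, rj = system.radius[i], system.radius[j]
    if cohesion is not None:
        A = cohesion.table[system.types[i].astype(int),
                           system.types[j].astype(int)]
    else:
        A = np.zeros(len(pairs))
    out[:, 0] = (A / 6.0) * 64.0 * ri**3 * rj**3
    out[:, 1] = 4.0 * ri * rj
    cut = cutoff_factor * np.minimum(ri, rj) + ri + rj
    out[:, 2] = cut * cut
    out[:, 3] = ri + rj
    mi, mj = system.mass[i], system.mass[j]
    out[:, 4] = mi * mj / (mi + mj)
    return out


@njit(cache=True, fastmath=True)
def _pair_forces(pos, vel, pairs, shear, pairdat, kn, kt, gn, gt,
                 s_min, box, perx, pery, dt, vmask, force):
    """Accumulate contact + cohesive pair forces; returns virial sum W_xz.

    ``pairdat`` is the per-pair constant table from
    :func:`build_pair_data`.  ``shear`` is advanced by dt (tangential
    history) and cleared on separation; pass dt = 0 for a pure force
    evaluation.  The virial sum only counts pairs whose two members are
    flagged in ``vmask`` (the stress is measured over the attached
    biofilm, not flying debris).
    """
    w_xz = 0.0
    for k in range(pairs.shape[0]):
        i = pairs[k, 0]
        j = pairs[k, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        dx, dy = _min_image(dx, dy, box[0], box[1], perx, pery)
        d2 = dx * dx + dy * dy + dz * dz
        if d2 > pairdat[k, 2] or d2 <= 0.0:  # beyond cutoff: no forces
            if dt > 0.0:
                shear[k, 0] = 0.0
                shear[k, 1] = 0.0
                shear[k, 2] = 0.0
            continue
        dist = math.sqrt(d2)
        sumr = pairdat[k, 3]
        s = dist - sumr
        inv = 1.0 / dist
        nx = dx * inv
        ny = dy * inv
        nz = dz * inv
        fx = 0.0
        fy = 0.0
        fz = 0.0
        if s < 0.0:  # contact
            delta = -s
            m_eff = pairdat[k, 4]
            vrx = vel[i, 0] - vel[j, 0]
            vry = vel[i, 1] - vel[j, 1]
            vrz = vel[i, 2] - vel[j, 2]
            vn = vrx * nx + vry * ny + vrz * nz
            vtx = vrx - vn * nx
            vty = vry - vn * ny
            vtz = vrz - vn * nz
            # normal spring + dashpot
            fn = -kn * delta - gn * m_eff * delta * vn
            fx += fn * nx
            fy += fn * ny
            fz += fn * nz
            # tangential history spring + dashpot
            if dt > 0.0:
                sx = shear[k, 0] + vtx * dt
                sy = shear[k, 1] + vty * dt
                sz = shear[k, 2] + vtz * dt
                # keep history in the tangent plane
                sn = sx * nx + sy * ny + sz * nz
                sx -= sn * nx
                sy -= sn * ny
                sz -= sn * nz
                shear[k, 0] = sx
                shear[k, 1] = sy
                shear[k, 2] = sz
            fx += -kt * shear[k, 0] - gt * m_eff * delta * vtx
            fy += -kt * shear[k, 1] - gt * m_eff * delta * vty
            fz += -kt * shear[k, 2] - gt * m_eff * delta * vtz
        else:
            if dt > 0.0:
                shear[k, 0] = 0.0
                shear[k, 1] = 0.0
                shear[k, 2] = 0.0
        coh_c = pairdat[k, 0]
        if coh_c > 0.0:
            se = s if s > s_min else s_min
            q = se * (se + 2.0 * sumr)
            t1 = q + pairdat[k, 1]
            mag = coh_c * (se + sumr) / (q * q * t1 * t1)
            fx += mag * nx
            fy += mag * ny
            fz += mag * nz
        force[i, 0] += fx
        force[i, 1] += fy
        force[i, 2] += fz
        force[j, 0] -= fx
        force[j, 1] -= fy
        force[j, 2] -= fz
        if vmask[i] != 0 and vmask[j] != 0:
            # virial: (r_i - r_j)_x * f_on_i_z = (-dx) * fz
            w_xz += (-dx) * fz
    return w_xz


@njit(cache=True, fastmath=True)
def _run_substeps(pos, vel, force, rad, mass, mobile, pairs, shear, pairdat,
                  kn, kt, gn, gt, s_min, box, perx, pery,
                  drag_c, u_fluid, f_lift, nsub, dt, vmask):
    """Advance ``nsub`` velocity-Verlet steps with frozen fluid data.

    Fluid-particle forcing during the block: linearised drag
    drag_c[i] * (u_fluid[i] - v[i])  (coefficient frozen at block start)
    plus the frozen lift vector.  The drag term enters each half-kick
    implicitly, so arbitrarily large drag coefficients (small particles,
    dense cells) cannot destabilise the integration.  One pair-force
    evaluation per step (the previous step's non-drag force seeds the
    first half-kick); ``force`` carries pair + lift forces only.
    Returns the virial pair sum W_xz of the final evaluation.
    """
    n = pos.shape[0]
    half = 0.5 * dt
    w_xz = 0.0
    for _ in range(nsub):
        for i in range(n):
            if mobile[i]:
                hm = half / mass[i]
                denom = 1.0 + hm * drag_c[i]
                vel[i, 0] = (vel[i, 0] + hm * (force[i, 0]
                             + drag_c[i] * u_fluid[i, 0])) / denom
                vel[i, 1] = (vel[i, 1] + hm * (force[i, 1]
                             + drag_c[i] * u_fluid[i, 1])) / denom
                vel[i, 2] = (vel[i, 2] + hm * (force[i, 2]
                             + drag_c[i] * u_fluid[i, 2])) / denom
                pos[i, 0] += vel[i, 0] * dt
                pos[i, 1] += vel[i, 1] * dt
                pos[i, 2] += vel[i, 2] * dt
                if perx:
                    pos[i, 0] %= box[0]
                if pery:
                    pos[i, 1] %= box[1]
                # hard floor / ceiling keep agents inside the channel
                if pos[i, 2] < rad[i]:
                    pos[i, 2] = rad[i]
                    if vel[i, 2] < 0.0:
                        vel[i, 2] = 0.0
                elif pos[i, 2] > box[2] - rad[i]:
                    pos[i, 2] = box[2] - rad[i]
                    if vel[i, 2] > 0.0:
                        vel[i, 2] = 0.0
        force[:] = 0.0
        w_xz = _pair_forces(pos, vel, pairs, shear, pairdat, kn, kt,
                            gn, gt, s_min, box, perx, pery,
                            dt, vmask, force)
        for i in range(n):
            if mobile[i]:
                force[i, 0] += f_lift[i, 0]
                force[i, 1] += f_lift[i, 1]
                force[i, 2] += f_lift[i, 2]
                hm = half / mass[i]
                denom = 1.0 + hm * drag_c[i]
                vel[i, 0] = (vel[i, 0] + hm * (force[i, 0]
                             + drag_c[i] * u_fluid[i, 0])) / denom
                vel[i, 1] = (vel[i, 1] + hm * (force[i, 1]
                             + drag_c[i] * u_fluid[i, 1])) / denom
                vel[i, 2] = (vel[i, 2] + hm * (force[i, 2]
                             + drag_c[i] * u_fluid[i, 2])) / denom
            else:
                vel[i, 0] = 0.0
                vel[i, 1] = 0.0
                vel[i, 2] = 0.0
    return w_xz


def stability_dt(system: ParticleSystem, cp: ContactParams,
                 factor: float = 0.05) -> float:
    """Spring-dashpot stability step  factor * sqrt(m_min / k_n)."""
    mobile = system.mobile
    m_min = float(system.mass[mobile].min()) if mobile.any() \
        else float(system.mass.min())
    return factor * math.sqrt(m_min / cp.k_n)


def step_dem(system: ParticleSystem, dt: float, force_hook=None,
             contact: ContactParams | None = None,
             cohesion: CohesionMatrix | None = None,
             cutoff_factor: float = 5.0,
             neighbors: NeighborState | None = None,
             n_steps: int = 1) -> ParticleSystem:
    """Advance the system ``n_steps`` velocity-Verlet steps of size ``dt``.

    ``force_hook(system) -> (N, 3)`` adds external per-particle forces
    (evaluated once per step).  Wall particles stay immobile; cyclic axes
    wrap.  Raises when dt exceeds the spring stability bound
    0.1 * sqrt(m_min / k_n).
    """
    sys_ = system.copy()
    if contact is not None:
        bound = stability_dt(sys_, contact, factor=0.1)
        if dt > bound:
            raise ValueError(
                f"dt={dt:.3e} exceeds stability bound {bound:.3e} s")
    if contact is not None or cohesion is not None:
        if neighbors is None:
            cut = cutoff_factor * float(sys_.radius.min())
            neighbors = NeighborState(sys_, cut)
        pairs = neighbors.pairs
        pairdat = build_pair_data(sys_, pairs, cohesion, cutoff_factor)
        cp = contact if contact is not None else ContactParams(0.0, 0.0, 0.0, 0.0)
        s_min = cohesion.s_min if cohesion is not None else 1e-9
    else:
        pairs = np.empty((0, 2), dtype=np.int64)
        pairdat = np.zeros((0, 5))
        cp = ContactParams(0.0, 0.0, 0.0, 0.0)
        s_min = 1e-9
        neighbors = None
    shear = neighbors.shear if neighbors is not None else np.zeros((0, 3))
    mobile = sys_.mobile
    box = sys_.domain
    perx, pery = sys_.periodic_axes[0], sys_.periodic_axes[1]
    half = 0.5 * dt

    vmask = np.ones(sys_.n, dtype=np.uint8)

    def eval_forces():
        sys_.force[:] = 0.0
        _pair_forces(sys_.pos, sys_.vel, pairs, shear,
                     pairdat, cp.k_n, cp.k_t, cp.gamma_n, cp.gamma_t, s_min,
                     box, perx, pery, dt, vmask, sys_.force)
        if force_hook is not None:
            sys_.force[mobile] += np.asarray(force_hook(sys_))[mobile]

    eval_forces()
    for _ in range(n_steps):
        sys_.vel[mobile] += sys_.force[mobile] / sys_.mass[mobile, None] * half
        sys_.pos[mobile] += sys_.vel[mobile] * dt
        sys_.wrap()
        eval_forces()
        sys_.vel[mobile] += sys_.force[mobile] / sys_.mass[mobile, None] * half
        sys_.vel[~mobile] = 0.0
    return sys_


def _pair_strengths(system: ParticleSystem, pairs: np.ndarray,
                    cohesion: CohesionMatrix) -> np.ndarray:
    """Per-pair cohesive strength from the type-pair lookup."""
    if len(pairs) == 0:
        return np.zeros(0)
    return cohesion.table[system.types[pairs[:, 0]].astype(int),
                          system.types[pairs[:, 1]].astype(int)]
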