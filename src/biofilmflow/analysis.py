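"""Derived mechanical observables of the simulated biofilm.

Covers the full post-processing chain of the flow experiments:

* cluster detection (connected components over cohesive-bond gaps) and
  detachment classification -- *erosion* for clusters below 1000
  particles, *sloughing* for 1000 and above;
* the detachment rate coefficient: detached biofilm volume over total
  biofilm volume per millisecond, within the initial detachment window
  (default 14 ms);
* shear strain as the tilt of the biofilm's leading edge measured on
  spanwise planes, and the global shear stress sigma_xz from the pair
  virial (plus an optional kinetic term);
* the apparent shear modulus G = sigma_xz / alpha at small strain
  (< 0.1), a one-term Prony-series viscoelastic fit
  G(t) = G_eq + G1 exp(-t/tau) through the ramp-loading hereditary
  integral (eta = G1 * tau), the post-unloading recovery fraction, and
  the hysteresis-loop energy density of a loading/unloading cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import scipy.optimize
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
from scipy.spatial import cKDTree

from .core import ContactParams, CohesionMatrix, ParticleSystem, ParticleType
from . import dem

__all__ = [
    "DetachmentKind",
    "DetachmentEvent",
    "StressStrainRecord",
    "ViscoelasticFit",
    "Cluster",
    "find_clusters",
    "classify_detachment",
    "detachment_rate_coefficient",
    "shear_strain",
    "global_shear_stress",
    "apparent_shear_modulus",
    "prony_fit",
    "prony_stress",
    "recovery_fraction",
    "hysteresis_area",
    "SLOUGHING_THRESHOLD",
]

SLOUGHING_THRESHOLD = 1000  # particles; below -> erosion


class DetachmentKind(Enum):
    EROSION = "erosion"
    SLOUGHING = "sloughing"


@dataclass(frozen=True)
class DetachmentEvent:
    """A cluster first losing wall connectivity."""

    time: float  # s
    particle_ids: frozenset
    volume: float  # m3

    @property
    def size(self) -> int:
        return len(self.particle_ids)

    @property
    def kind(self) -> DetachmentKind:
        return classify_detachment(self.size)


@dataclass(frozen=True)
class StressStrainRecord:
    """One sample of the global stress-strain trace.

    ``alpha`` is the mean deformation angle over the measurement planes
    relative to the undeformed reference.
    """

    t: float
    sigma_xz: float
    alpha: float
    plane_angles: tuple = ()


@dataclass(frozen=True)
class ViscoelasticFit:
    """One-term Prony shear relaxation parameters."""

    G_eq: float  # Pa
    G1: float  # Pa
    tau: float  # s
    residual: float
    G_apparent: float = float("nan")

    @property
    def eta(self) -> float:
        """Viscosity of the Maxwell arm, G1 * tau (Pa s)."""
        return self.G1 * self.tau


# -- clusters and detachment ----------------------------------------------

@dataclass(frozen=True)
class Cluster:
    """A connected component of cohesively bonded particles."""

    indices: np.ndarray  # positions into the ParticleSystem arrays
    particle_ids: frozenset
    attached: bool
    volume: float

    @property
    def size(self) -> int:
        return len(self.particle_ids)


def find_clusters(system: ParticleSystem, bond_gap: float) -> list[Cluster]:
    """Connected components of the bond graph (surface gap < ``bond_gap``).

    Components containing a wall particle are *attached*; all others are
    *detached*.  Pure-wall components are not reported.  Returned sorted
    by size, largest first.
    """
    if bond_gap <= 0:
        raise ValueError("bond_gap must be positive")
    n = system.n
    if n == 0:
        return []
    pairs = dem.build_neighbor_list(system, bond_gap)
    adj = sp.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    ncomp, labels = csgraph.connected_components(adj, directed=False)
    wall = system.types == int(ParticleType.WALL)
    vols = system.volumes()
    out = []
    for c in range(ncomp):
        members = np.where(labels == c)[0]
        live = members[~wall[members]]
        if len(live) == 0:
            continue
        out.append(Cluster(
            indices=live,
            particle_ids=frozenset(int(i) for i in system.ids[live]),
            attached=bool(wall[members].any()),
            volume=float(vols[live].sum()),
        ))
    out.sort(key=lambda c: c.size, reverse=True)
    return out


def classify_detachment(size: int) -> DetachmentKind:
    """Erosion below the 1000-particle threshold, sloughing at or above."""
    if size < 1:
        raise ValueError("cluster size must be at least 1")
    return (DetachmentKind.EROSION if size < SLOUGHING_THRESHOLD
            else DetachmentKind.SLOUGHING)


def detachment_rate_coefficient(events, V_total: float,
                                window: float = 14.0e-3) -> float:
    """Detached volume fraction per millisecond over the initial window.

    (sum of detached cluster volumes with time <= window) / V_total,
    divided by the window length in ms.  Units: 1/ms.
    """
    if V_total <= 0:
        raise ValueError("total biofilm volume must be positive")
    if window <= 0:
        raise ValueError("window must be positive")
    v = sum(e.volume for e in events if e.time <= window)
    return (v / V_total) / (window * 1.0e3)


# -- strain and stress -----------------------------------------------------

DEFAULT_PLANES = (5.0e-6, 15.0e-6, 25.0e-6)


def _front_edge_angle(pos: np.ndarray, y0: float, half_width: float,
                      z_bin: float) -> float | None:
    """Tilt (rad, from the wall-normal) of the leading-edge line of the
    slab |y - y0| < half_width; None when the slab holds no biofilm."""
    sel = np.abs(pos[:, 1] - y0) < half_width
    if not sel.any():
        return None
    pts = pos[sel]
    zb = (pts[:, 2] / z_bin).astype(np.int64)
    zb -= zb.min()
    nb = int(zb.max()) + 1
    lead = np.full(nb, -np.inf)
    np.maximum.at(lead, zb, pts[:, 0])
    used = np.isfinite(lead)
    if used.sum() < 2:
        return None
    z = (np.arange(nb)[used] + 0.5) * z_bin
    x = lead[used]
    # Theil-Sen slope dx/dz: the median of pairwise slopes is robust to
    # single outlier bins of the rough discrete surface (a plain least
    # squares line can jump by ~0.2 rad when one bin's leading particle
    # changes identity)
    dz = z[:, None] - z[None, :]
    dx = x[:, None] - x[None, :]
    iu = np.triu_indices(len(z), k=1)
    slope = float(np.median(dx[iu] / dz[iu]))
    return math.atan(slope)


def _aligned_positions(system: ParticleSystem, reference: ParticleSystem,
                       mask=None):
    """Unwrapped current positions of the live particles shared with the
    reference (periodic displacements mapped to the minimum image so a
    particle crossing a cyclic boundary does not jump)."""
    live_now = np.where(system.mobile)[0]
    live_ref = np.where(reference.mobile)[0]
    _, i_now, i_ref = np.intersect1d(system.ids[live_now],
                                     reference.ids[live_ref],
                                     return_indices=True)
    idx_now, idx_ref = live_now[i_now], live_ref[i_ref]
    disp = system.pos[idx_now] - reference.pos[idx_ref]
    for ax in range(3):
        if system.periodic_axes[ax]:
            L = system.domain[ax]
            disp[:, ax] -= L * np.round(disp[:, ax] / L)
    pos = reference.pos[idx_ref] + disp
    pos[:, 2] = system.pos[idx_now, 2]
    ref = reference.pos[idx_ref]
    if mask is not None:
        keep = np.asarray(mask)[idx_now].astype(bool)
        pos, ref = pos[keep], ref[keep]
    return pos, ref


def shear_strain(system: ParticleSystem, reference: ParticleSystem,
                 planes=DEFAULT_PLANES, half_width: float = 3.0e-6,
                 z_bin: float = 1.0e-6, mask=None,
                 max_displacement: float | None = 15.0e-6) -> float:
    """Mean leading-edge deformation angle relative to the reference.

    For each measurement plane the frontmost particle per z-bin defines
    the biofilm's leading edge; a least-squares line through those points
    gives the edge's tilt from the wall-normal.  The reference
    configuration's tilt is subtracted and the angles are averaged over
    planes (empty slabs are skipped).

    ``mask`` restricts the estimate to flagged particles (e.g. the
    still-attached biofilm) and ``max_displacement`` drops particles that
    moved farther than that from their reference position -- detached
    debris advected downstream no longer describes the deforming colony.
    """
    pos, ref = _aligned_positions(system, reference, mask=mask)
    if max_displacement is not None and len(pos):
        keep = np.linalg.norm(pos - ref, axis=1) < max_displacement
        pos, ref = pos[keep], ref[keep]
    angles = []
    for y0 in planes:
        a_now = _front_edge_angle(pos, y0, half_width, z_bin)
        a_ref = _front_edge_angle(ref, y0, half_width, z_bin)
        if a_now is None or a_ref is None:
            continue
        angles.append(a_now - a_ref)
    if not angles:
        raise ValueError("no measurement plane intersects the biofilm")
    return float(np.mean(angles))


def global_shear_stress(system: ParticleSystem, V_biofilm: float,
                        contact: ContactParams | None = None,
                        cohesion: CohesionMatrix | None = None,
                        cutoff_factor: float = 5.0,
                        include_kinetic: bool = True,
                        pair_virial_xz: float | None = None) -> float:
    """Global virial shear stress sigma_xz over the biofilm volume.

    sigma_xz = (1/V) [ sum_pairs (r_i - r_j)_x f_ij,z
                       + sum_i m_i v_i,x v_i,z ]

    The pair sum runs over contact + cohesive interactions.  Pass
    ``pair_virial_xz`` to reuse a pair sum already accumulated by the
    integrator instead of recomputing forces.
    """
    if V_biofilm <= 0:
        raise ValueError("biofilm volume must be positive")
    if pair_virial_xz is None:
        if contact is None and cohesion is None:
            pair_virial_xz = 0.0
        else:
            cut = cutoff_factor * float(system.radius.min())
            pairs = dem.build_neighbor_list(system, cut, exclude_wall_wall=True)
            pairdat = dem.build_pair_data(system, pairs, cohesion,
                                          cutoff_factor)
            cp = contact or ContactParams(0.0, 0.0, 0.0, 0.0)
            s_min = cohesion.s_min if cohesion is not None else 1e-9
            force = np.zeros_like(system.force)
            shear = np.zeros((len(pairs), 3))
            vmask = np.ones(system.n, dtype=np.uint8)
            pair_virial_xz = dem._pair_forces(
                system.pos, system.vel, pairs,
                shear, pairdat, cp.k_n, cp.k_t, cp.gamma_n, cp.gamma_t, s_min,
                system.domain, system.periodic_axes[0],
                system.periodic_axes[1], 0.0, vmask, force)
    w = float(pair_virial_xz)
    if include_kinetic:
        live = system.mobile
        w += float((system.mass[live] * system.vel[live, 0]
                    * system.vel[live, 2]).sum())
    return w / V_biofilm


# -- viscoelastic characterisation -----------------------------------------

def apparent_shear_modulus(records, strain_cap: float = 0.1,
                           strain_floor: float = 0.0) -> float:
    """Small-strain modulus: slope of sigma_xz vs alpha through the origin.

    Least squares over samples with ``strain_floor`` < alpha <
    ``strain_cap`` (G = sum(sigma alpha) / sum(alpha^2)).  A non-zero
    floor excludes samples below the resolution of the leading-edge
    strain estimator, which otherwise inject noise-dominated ratios.
    """
    t, sigma, alpha = _as_arrays(records)
    sel = (alpha > strain_floor) & (alpha < strain_cap)
    if sel.sum() < 2:
        raise ValueError("need at least two samples below the strain cap")
    a, s = alpha[sel], sigma[sel]
    return float((s @ a) / (a @ a))


def _as_arrays(records):
    """(t, sigma, alpha) arrays from a record list or a 3-tuple of arrays."""
    if isinstance(records, tuple) and len(records) == 3:
        t, s, a = (np.asarray(x, float) for x in records)
        return t, s, a
    t = np.array([r.t for r in records])
    s = np.array([r.sigma_xz for r in records])
    a = np.array([r.alpha for r in records])
    return t, s, a


def prony_stress(t: np.ndarray, alpha: np.ndarray, G_eq: float, G1: float,
                 tau: float) -> np.ndarray:
    """Stress response of G(t) = G_eq + G1 exp(-t/tau) to the measured
    strain history ``alpha(t)`` via the hereditary integral
    sigma(t) = int_0^t G(t - s) dalpha/ds ds  (piecewise-linear strain)."""
    t = np.asarray(t, float)
    alpha = np.asarray(alpha, float)
    tau = max(tau, 1e-12)
    d_alpha = np.diff(alpha, prepend=alpha[0] * 0.0)
    t_mid = t - 0.5 * np.diff(t, prepend=t[0] * 0.0)
    # sigma(t_k) = sum_{m<=k} G(t_k - t_mid_m) dalpha_m
    dt_mat = t[:, None] - t_mid[None, :]
    g = np.where(dt_mat >= 0.0, G_eq + G1 * np.exp(-np.maximum(dt_mat, 0.0) / tau),
                 0.0)
    mask = np.tril(np.ones((len(t), len(t))))
    return (g * mask) @ d_alpha


def prony_fit(series, t_loads=None) -> ViscoelasticFit:
    """Joint one-term Prony fit over records at one or more loading rates.

    ``series`` is a list of stress-strain traces (each a record list or a
    ``(t, sigma, alpha)`` tuple) covering loading and relaxation.  The
    three parameters (G_eq, G1, tau) are fitted jointly by least squares
    of the hereditary-integral stress against the measured stress, each
    trace normalised by its peak stress so different rates weigh equally.
    Raises on non-convergence.
    """
    if isinstance(series, tuple) and len(series) == 3 \
            and not isinstance(series[0], (list, tuple)):
        series = [series]
    data = [_as_arrays(s) for s in series]
    scales = [max(np.abs(s).max(), 1e-30) for (_, s, _) in data]

    def residuals(p):
        log_geq, log_g1, log_tau = p
        geq, g1, tau = math.exp(log_geq), math.exp(log_g1), math.exp(log_tau)
        out = []
        for (t, s, a), sc in zip(data, scales):
            out.append((prony_stress(t, a, geq, g1, tau) - s) / sc)
        return np.concatenate(out)

    # initial guesses: plateau modulus from the trace tails, relaxation
    # time from the trace span
    tails = [s[-1] / a[-1] if abs(a[-1]) > 1e-12 else 1.0 for (_, s, a) in data]
    geq0 = max(float(np.median(tails)), 1e-3)
    peaks = [np.max(np.abs(s)) / max(np.max(np.abs(a)), 1e-12)
             for (_, s, a) in data]
    g10 = max(float(np.median(peaks)) - geq0, 1e-3)
    tau0 = max(float(np.median([t[-1] for (t, _, _) in data])) / 10.0, 1e-6)
    p0 = np.clip(np.log([geq0, g10, tau0]), -18.0, 18.0)
    res = scipy.optimize.least_squares(residuals, p0, method="trf",
                                       bounds=(-20.0, 20.0), xtol=1e-12,
                                       ftol=1e-12, max_nfev=2000)
    if not res.success:
        raise RuntimeError(f"Prony fit failed: {res.message}; "
                           f"residual {np.linalg.norm(res.fun):.3e}")
    geq, g1, tau = np.exp(res.x)
    return ViscoelasticFit(G_eq=float(geq), G1=float(g1), tau=float(tau),
                           residual=float(np.linalg.norm(res.fun)))


def recovery_fraction(trace, t_load: float) -> float:
    """Percent strain recovered after unloading:
    100 * (alpha(t_load) - alpha(end)) / alpha(t_load)."""
    t, _, alpha = _as_arrays(trace) if not isinstance(trace, tuple) \
        else (np.asarray(trace[0], float), None, np.asarray(trace[1], float)) \
        if len(trace) == 2 else _as_arrays(trace)
    if t[-1] <= t_load:
        raise ValueError("trace must extend beyond the loading phase")
    a_load = float(np.interp(t_load, t, alpha))
    if a_load == 0.0:
        raise ValueError("zero strain at the end of loading")
    return 100.0 * (a_load - float(alpha[-1])) / a_load


def hysteresis_area(loop) -> float:
    """Energy density (J/m3) enclosed by an ordered (alpha, sigma) loop.

    Signed shoelace area of the polygon closed by joining the last sample
    back to the first; the sign convention makes a dissipative
    load-then-unload cycle (unloading path below the loading path)
    positive.
    """
    pts = np.asarray(loop, float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least three (alpha, sigma) samples")
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    shoelace = 0.5 * float(np.sum(x * yn - xn * y))  # counter-clockwise > 0
    return -shoelace
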