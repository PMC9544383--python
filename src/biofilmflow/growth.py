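"""Individual-based pre-growth of a biofilm colony on the substratum.

Growth and flow are decoupled: the colony is grown under static
conditions (default 5.3 days) and the resulting particle configuration
is handed to the flow protocols.  Only three processes are modeled:

* **growth** -- each cell's volume increases at the Monod rate
  mu = mu_max * S / (K_s + S), with multiplicative lognormal noise
  representing biological variability;
* **division** -- a cell splits at diameter 1.4 um into two equal-volume
  daughters placed along a random axis (parent volume conserved exactly);
* **EPS production** -- each cell accretes an EPS shell in proportion to
  its own growth and excretes the shell as a discrete EPS agent next to
  itself once the shell-to-cell volume ratio passes a threshold.

EPS bookkeeping uses a competitive yield split: of the substrate COD
consumed, a fraction Y_eps becomes EPS and Y_tot - Y_eps becomes
biomass, so the EPS-to-biomass volume ratio scales like
kappa = c * Y_eps / (Y_tot - Y_eps).  The two constants (Y_tot and the
COD-to-volume factor c) are calibrated once so that sweeping the EPS
yield over 0.12-0.22 spans EPS volume ratios of roughly 20%-51%, the
published range for this sweep.

After every growth step a short mechanical relaxation (overlap-removal
iterations) restores a near-packed configuration; the time scales of
growth (hours) and mechanics (sub-ms) are separated by many orders of
magnitude, so quasi-static relaxation replaces explicit dynamics here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core import ParticleSystem, ParticleType, RADIUS_MAX, RADIUS_MIN

__all__ = [
    "GrowthParams",
    "grow_biofilm",
    "eps_volume_ratio",
    "morphology_metrics",
]

DAY = 86400.0


@dataclass(frozen=True)
class GrowthParams:
    """Kinetic and bookkeeping constants of the pre-growth model.

    ``Y_eps`` is the EPS growth yield (g COD_EPS / g COD_S, published
    sweep range 0.12-0.22); ``Y_tot`` the total assimilated yield of the
    competitive split; ``eps_cod_to_volume`` the calibrated COD-to-volume
    conversion ratio of EPS relative to biomass.  ``S`` is the (constant)
    bulk substrate concentration -- no transport gradients are modeled.
    """

    Y_eps: float = 0.18
    mu_max: float = 1.2e-5  # 1/s  (~1 doubling / 16 h at saturation)
    K_s: float = 3.5e-3  # kg/m3
    S: float = 3.0e-2  # kg/m3
    division_diameter: float = 1.4e-6  # m
    eps_excretion_ratio: float = 0.2  # shell/cell volume threshold
    t_grow: float = 5.3 * DAY
    seed: int = 0
    Y_tot: float = 0.38
    eps_cod_to_volume: float = 0.84
    dt_grow: float = 1200.0  # s
    growth_noise: float = 0.10  # lognormal sigma per step
    founder_radius_spread: tuple = (0.45e-6, 0.55e-6)
    founder_patch_radius: float = 6.0e-6  # m, colony seeding disc
    wall_spacing: float = 1.0e-6
    wall_radius: float = 0.5e-6
    max_fill_height: float = 0.85  # stop growth at this fraction of H
    #: optional stop criterion: halt once the biofilm (bacteria + EPS)
    #: volume reaches this value (m^3).  Lets colonies with different
    #: EPS yields be grown to matched size, removing the size confound
    #: from cross-yield mechanical comparisons.
    target_volume: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.Y_eps < 1.0:
            raise ValueError("Y_eps must lie in [0, 1)")
        if self.Y_eps >= self.Y_tot:
            raise ValueError("Y_eps must be below the total yield Y_tot")
        if self.division_diameter > 1.4e-6 + 1e-12:
            raise ValueError("division diameter exceeds the 1.4 um agent bound")
        if self.t_grow <= 0:
            raise ValueError("t_grow must be positive")

    @property
    def kappa(self) -> float:
        """EPS volume produced per unit biomass volume produced."""
        return self.eps_cod_to_volume * self.Y_eps / (self.Y_tot - self.Y_eps)

    @property
    def monod_rate(self) -> float:
        return self.mu_max * self.S / (self.K_s + self.S)


def _radius_from_volume(v):
    return (3.0 * np.asarray(v) / (4.0 * math.pi)) ** (1.0 / 3.0)


def _relax_overlaps(system: ParticleSystem, rng, max_iter: int = 40,
                    tol_frac: float = 0.05) -> None:
    """Quasi-static overlap removal: push overlapping pairs apart along
    their normal (wall particles fixed) until the worst overlap is below
    ``tol_frac`` of the smaller radius."""
    box = system.domain
    mobile = system.mobile
    for _ in range(max_iter):
        rmax = float(system.radius.max())
        pts = system.pos.copy()
        pts[:, 0] %= box[0]
        pts[:, 1] %= box[1]
        tree = cKDTree(pts, boxsize=[box[0], box[1], 1e9])
        pairs = tree.query_pairs(2.0 * rmax, output_type="ndarray")
        if len(pairs) == 0:
            return
        i, j = pairs[:, 0], pairs[:, 1]
        d = pts[j] - pts[i]
        for ax in (0, 1):
            d[:, ax] -= box[ax] * np.round(d[:, ax] / box[ax])
        dist = np.linalg.norm(d, axis=1)
        dist = np.where(dist == 0.0, 1e-12, dist)
        overlap = system.radius[i] + system.radius[j] - dist
        hit = overlap > 0.0
        if not hit.any():
            return
        rmin_pair = np.minimum(system.radius[i], system.radius[j])
        if float((overlap[hit] / rmin_pair[hit]).max()) < tol_frac:
            return
        shift = 0.55 * 0.5 * overlap[hit, None] * d[hit] / dist[hit, None]
        disp = np.zeros_like(system.pos)
        np.add.at(disp, i[hit], -shift)
        np.add.at(disp, j[hit], shift)
        disp[~mobile] = 0.0
        system.pos += disp
        system.pos[:, 2] = np.maximum(system.pos[:, 2], system.radius)
        system.wrap()


def _add_wall_layer(system: ParticleSystem, params: GrowthParams) -> None:
    sp, r = params.wall_spacing, params.wall_radius
    nx = max(int(round(system.domain[0] / sp)), 1)
    ny = max(int(round(system.domain[1] / sp)), 1)
    xs = (np.arange(nx) + 0.5) * system.domain[0] / nx
    ys = (np.arange(ny) + 0.5) * system.domain[1] / ny
    for x in xs:
        for y in ys:
            system.add(ParticleType.WALL, (x, y, r), r)


def grow_biofilm(params: GrowthParams, n_founders: int = 5,
                 domain=(50e-6, 20e-6, 25e-6)) -> ParticleSystem:
    """Grow a colony from ``n_founders`` cells seeded on the substratum.

    Deterministic for a given ``params.seed``.  Growth halts with a
    warning if the colony reaches ``max_fill_height`` of the channel.
    """
    if n_founders < 1:
        raise ValueError("need at least one founder cell")
    rng = np.random.default_rng(params.seed)
    system = ParticleSystem(domain)
    _add_wall_layer(system, params)
    wall_top = 2.0 * params.wall_radius
    cx, cy = system.domain[0] * 0.35, system.domain[1] * 0.5
    for _ in range(n_founders):
        ang = rng.uniform(0, 2 * math.pi)
        rad = params.founder_patch_radius * math.sqrt(rng.uniform())
        r = rng.uniform(*params.founder_radius_spread)
        pos = (cx + rad * math.cos(ang), cy + rad * math.sin(ang), wall_top + r * 0.8)
        system.add(ParticleType.BACTERIUM, pos, r)

    shells: dict[int, float] = {int(i): 0.0 for i in system.ids[system.mobile]}
    n_steps = max(int(round(params.t_grow / params.dt_grow)), 1)
    mu0 = params.monod_rate
    kappa = params.kappa
    theta = params.eps_excretion_ratio

    for _ in range(n_steps):
        if mu0 <= 0.0:
            break
        bact = np.where(system.mask(ParticleType.BACTERIUM))[0]
        if len(bact) == 0:
            break
        # -- growth with per-cell noise --
        noise = np.exp(rng.normal(0.0, params.growth_noise, len(bact)))
        gfac = np.exp(mu0 * params.dt_grow * noise)
        vol_old = (4.0 / 3.0) * math.pi * system.radius[bact] ** 3
        vol_new = vol_old * gfac
        dvol = vol_new - vol_old
        system.radius[bact] = _radius_from_volume(vol_new)
        system.mass[bact] = 1.0e3 * vol_new
        for idx, dv in zip(bact, dvol):
            pid = int(system.ids[idx])
            shells[pid] = shells.get(pid, 0.0) + kappa * dv

        # -- division --
        div = bact[2.0 * system.radius[bact] >= params.division_diameter]
        for idx in div:
            pid = int(system.ids[idx])
            vol = (4.0 / 3.0) * math.pi * system.radius[idx] ** 3
            r_d = _radius_from_volume(vol / 2.0)
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            parent_pos = system.pos[idx].copy()
            shell = shells.pop(pid, 0.0)
            # shrink parent in place into daughter 1
            system.radius[idx] = r_d
            system.mass[idx] = 1.0e3 * vol / 2.0
            system.pos[idx] = parent_pos - 0.5 * r_d * axis
            shells[pid] = shell / 2.0
            new_pos = parent_pos + 0.5 * r_d * axis
            new_pos[2] = max(new_pos[2], wall_top + 0.5 * r_d)
            new_id = system.add(ParticleType.BACTERIUM, new_pos, r_d)
            shells[new_id] = shell / 2.0

        # -- EPS excretion --
        bact = np.where(system.mask(ParticleType.BACTERIUM))[0]
        v_eps_min = (4.0 / 3.0) * math.pi * RADIUS_MIN**3
        for idx in bact:
            pid = int(system.ids[idx])
            shell = shells.get(pid, 0.0)
            vol = (4.0 / 3.0) * math.pi * system.radius[idx] ** 3
            # the shell must both pass the ratio threshold and be large
            # enough to form an agent within the allowed radius range
            if shell / vol > theta and shell >= v_eps_min:
                r_e = float(_radius_from_volume(shell))
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                pos = system.pos[idx] + (system.radius[idx] + r_e) * direction
                pos[2] = max(pos[2], wall_top + 0.5 * r_e)
                system.add(ParticleType.EPS, pos, r_e)
                shells[pid] = 0.0

        _relax_overlaps(system, rng)
        top = float(system.pos[system.mobile, 2].max())
        if top > params.max_fill_height * system.domain[2]:
            warnings.warn("growth halted: colony reached the channel ceiling",
                          RuntimeWarning, stacklevel=2)
            break
        if params.target_volume is not None and \
                float(system.volumes()[system.mobile].sum()) \
                >= params.target_volume:
            break
    system.vel[:] = 0.0
    return system


def eps_volume_ratio(system: ParticleSystem) -> float:
    """EPS volume divided by total biofilm (EPS + bacteria) volume."""
    vols = system.volumes()
    v_eps = float(vols[system.mask(ParticleType.EPS)].sum())
    v_bact = float(vols[system.mask(ParticleType.BACTERIUM)].sum())
    if v_eps + v_bact == 0.0:
        raise ValueError("empty biofilm: no bacteria or EPS agents")
    return v_eps / (v_eps + v_bact)


def morphology_metrics(system: ParticleSystem, bin_size: float = 1.0e-6) -> dict:
    """Surface-map morphology of the colony.

    Heights come from a column-wise top-surface map on an x-y grid
    (columns without biofilm are ignored); roughness is the mean absolute
    deviation of the surface height over its mean; porosity is one minus
    the particle volume filling of the occupied columns.
    """
    live = system.mobile
    if not live.any():
        raise ValueError("empty biofilm")
    pos, rad = system.pos[live], system.radius[live]
    nx = max(int(round(system.domain[0] / bin_size)), 1)
    ny = max(int(round(system.domain[1] / bin_size)), 1)
    ix = np.clip((pos[:, 0] / system.domain[0] * nx).astype(int), 0, nx - 1)
    iy = np.clip((pos[:, 1] / system.domain[1] * ny).astype(int), 0, ny - 1)
    top = np.full((nx, ny), -np.inf)
    np.maximum.at(top, (ix, iy), pos[:, 2] + rad)
    occupied = np.isfinite(top)
    heights = top[occupied]
    mean_h = float(heights.mean())
    roughness = float(np.abs(heights - mean_h).mean() / mean_h) if mean_h > 0 else 0.0
    col_area = (system.domain[0] / nx) * (system.domain[1] / ny)
    occ_volume = float(heights.sum() * col_area)
    v_part = float(((4.0 / 3.0) * math.pi * rad**3).sum())
    porosity = max(1.0 - v_part / occ_volume, 0.0) if occ_volume > 0 else 0.0
    return {
        "mean_height": mean_h,
        "max_height": float(heights.max()),
        "roughness": roughness,
        "porosity": porosity,
    }
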