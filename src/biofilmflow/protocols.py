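"""End-to-end flow experiments on a pre-grown biofilm.

Two protocols, mirroring the published study design:

* **steady flow** -- the pre-grown colony is exposed to a constant
  driving speed U for a fixed duration (default 40 ms); detachment
  events are logged and the detachment rate coefficient is evaluated
  over the initial 14 ms window;
* **deformation-recovery** -- the driving speed ramps from zero at a
  constant acceleration for 3 ms (loading) and is then set to zero for
  17 ms (unloading); the global stress-strain trace yields the apparent
  shear modulus, a one-term Prony fit (equilibrium modulus and
  viscosity), the recovery fraction and the hysteresis-loop area.

Time stepping interleaves one fluid projection step with ``substeps``
DEM velocity-Verlet steps; drag is linearised per particle at the start
of each fluid step so it stays responsive to the evolving particle
velocity inside the sub-step block.  During relaxation the fluid keeps
running with zero boundary speed and decays viscously; ``freeze_fluid``
in the config selects the literal stopped-flow reading instead.

Desk-scale fixture
------------------
Full-scale runs with the published stiffness (k_n = 1e3 N/m on
femtogram agents) imply ~1e9 integration steps per experiment and are
not reproducible interactively.  :func:`desk_config` therefore provides
a reduced study: the same geometry class (50 x 20 x 25 um channel), a
colony of a few hundred agents, the elastic constants scaled by 1e-7,
and the cohesive strengths scaled by 4e-3 with the clamp distance
raised to 20 nm (every pairwise ratio of the published cohesion table
is preserved, and the cohesive stiffness at the clamp stays below the
contact stiffness so the soft-sphere step remains stable).  All
qualitative trends -- detachment rate vs. velocity, EPS fraction
effects, rate stiffening, hysteresis -- are assessed at this scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import analysis, coupling, dem
from .analysis import DetachmentEvent, StressStrainRecord
from .core import (ParticleSystem, ParticleType, SimulationConfig,
                   make_cohesion_matrix, ContactParams)
from .fluid import BoundaryConditions, FluidGrid, step_fluid
from .growth import GrowthParams, grow_biofilm, morphology_metrics

__all__ = [
    "ExperimentResult",
    "run_steady_flow",
    "run_deformation_recovery",
    "run_replicates",
    "desk_config",
    "desk_biofilm",
    "DESK_COHESION_SCALE",
    "DESK_STIFFNESS_SCALE",
]

DESK_STIFFNESS_SCALE = 1.0e-7
DESK_COHESION_SCALE = 4.0e-3
DESK_S_MIN = 20.0e-9


@dataclass
class ExperimentResult:
    """Everything a flow experiment produces."""

    snapshots: list = field(default_factory=list)  # [(t, ParticleSystem)]
    stress_strain: list = field(default_factory=list)  # [StressStrainRecord]
    events: list = field(default_factory=list)  # [DetachmentEvent]
    summary: dict = field(default_factory=dict)
    #: smoothed (t, sigma, alpha) arrays truncated at any front-slough
    #: discontinuity; what the viscoelastic fits consume
    processed_trace: tuple | None = None

    def trace(self):
        """(t, sigma, alpha) arrays of the stress-strain record."""
        t = np.array([r.t for r in self.stress_strain])
        s = np.array([r.sigma_xz for r in self.stress_strain])
        a = np.array([r.alpha for r in self.stress_strain])
        return t, s, a


def _smooth(x: np.ndarray, w: int = 9) -> np.ndarray:
    """Centered moving average with edge shrinkage."""
    if len(x) < 3:
        return x
    w = min(w, len(x) | 1)
    kernel = np.ones(w) / w
    pad = w // 2
    xp = np.concatenate([np.full(pad, x[0]), x, np.full(pad, x[-1])])
    return np.convolve(xp, kernel, mode="valid")


def desk_config(**overrides) -> SimulationConfig:
    """The reduced-scale study conditions (see module docstring)."""
    contact = ContactParams(k_n=1.0e3 * DESK_STIFFNESS_SCALE,
                            k_t=1.0e3 * DESK_STIFFNESS_SCALE,
                            gamma_n=1.0e13, gamma_t=10.0)
    kw = dict(
        domain=(50e-6, 20e-6, 25e-6),
        grid=(10, 4, 5),
        dt_dem=4.0e-8,
        dt_fluid=2.0e-6,
        contact=contact,
        cohesion=make_cohesion_matrix(
            s_min=DESK_S_MIN).scaled(DESK_COHESION_SCALE),
        cohesion_cutoff_factor=2.0,
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


_COLONY_CACHE: dict = {}


def desk_biofilm(Y_eps: float = 0.18, seed: int = 0,
                 t_grow: float = 4.2e5, n_founders: int = 4,
                 target_volume: float | None = 1.0e-16,
                 domain=(50e-6, 20e-6, 25e-6)) -> ParticleSystem:
    """Grow the reduced test colony (a few hundred agents).

    Colonies are grown to a matched biofilm volume (default 1e-16 m^3)
    rather than a fixed time, so sweeps over the EPS yield compare
    colonies of equal size; ``t_grow`` caps the growth duration.
    Growth is deterministic per parameter set, so results are memoised
    per process (a copy is returned each call).
    """
    key = (Y_eps, seed, t_grow, n_founders, target_volume, tuple(domain))
    if key not in _COLONY_CACHE:
        params = GrowthParams(Y_eps=Y_eps, seed=seed, t_grow=t_grow,
                              target_volume=target_volume)
        _COLONY_CACHE[key] = grow_biofilm(params, n_founders=n_founders,
                                          domain=domain)
    return _COLONY_CACHE[key].copy()


class _CoupledRun:
    """Internal engine: one biofilm + config, advanced fluid step by
    fluid step with DEM sub-stepping and event/stress bookkeeping."""

    def __init__(self, biofilm: ParticleSystem, config: SimulationConfig,
                 sample_every: int = 10, detect_every: int = 50):
        self.cfg = config
        if not np.allclose(biofilm.domain, config.domain):
            raise ValueError("config domain does not match the biofilm domain")
        self.sys = biofilm.copy()
        self.reference = biofilm.copy()
        self.sample_every = sample_every
        self.detect_every = detect_every
        self.grid = FluidGrid(config.grid, config.domain, config.fluid,
                              mode="couette" if config.drive == "couette"
                              else "inlet")
        if config.drive == "inlet":
            self.sys.periodic_axes = (False, True, False)
        rmax = float(self.sys.radius.max())
        self.skin = 0.6e-6
        self.list_cutoff = config.cohesion_cutoff_factor * rmax + self.skin
        self.neighbors = dem.NeighborState(
            self.sys, self.list_cutoff,
            pair_cutoff_factor=config.cohesion_cutoff_factor, skin=self.skin)
        self._pairdat = dem.build_pair_data(
            self.sys, self.neighbors.pairs, config.cohesion,
            config.cohesion_cutoff_factor)
        self._pos_at_rebuild = self.sys.pos.copy()
        self.attached = np.ones(self.sys.n, dtype=bool)
        self.t = 0.0
        self.events: list[DetachmentEvent] = []
        self.records: list[StressStrainRecord] = []
        self._detached_ids: set[int] = set()
        live = self.sys.mobile
        self.V_particles = float(self.sys.volumes()[live].sum())
        morph = morphology_metrics(self.sys)
        # stress normalisation volume: particle volume corrected by the
        # colony porosity (envelope volume of the biofilm)
        self.V_biofilm = self.V_particles / max(1.0 - morph["porosity"], 0.05)
        w = self.sys.domain[1]
        self.planes = tuple(np.array([1.0 / 6.0, 0.5, 5.0 / 6.0]) * w)
        self._pair_w_xz = 0.0
        self._step_count = 0
        self._settling = False
        # baseline: agents loose at t = 0 (growth artifacts) are recorded
        # as pre-detached, not as flow-induced events
        labels = self._bond_components()
        wall = self.sys.types == int(ParticleType.WALL)
        attached = np.isin(labels, np.unique(labels[wall]))
        self.attached = attached | wall
        self._detached_ids = set(
            int(i) for i in self.sys.ids[~self.attached & self.sys.mobile])

    def settle(self, duration: float = 4.0e-4) -> None:
        """Quiescent pre-equilibration: run the coupled system with zero
        driving so contacts and cohesive bonds relax, then re-zero the
        experiment clock and reference configuration."""
        self._settling = True
        try:
            self.advance(duration)
        finally:
            self._settling = False
        self.t = 0.0
        self._step_count = 0
        self.records.clear()
        self.events.clear()
        self.reference = self.sys.copy()
        live = self.sys.mobile
        self.V_particles = float(self.sys.volumes()[live].sum())
        labels = self._bond_components()
        wall = self.sys.types == int(ParticleType.WALL)
        attached = np.isin(labels, np.unique(labels[wall]))
        self.attached = attached | wall
        self._detached_ids = set(
            int(i) for i in self.sys.ids[~self.attached & self.sys.mobile])

    # -- bookkeeping -------------------------------------------------------
    def _bond_components(self):
        """Connected components over the current pair list at bond_gap."""
        import scipy.sparse as sp
        import scipy.sparse.csgraph as csgraph
        pairs = self.neighbors.pairs
        n = self.sys.n
        if len(pairs):
            d = self.sys.pos[pairs[:, 1]] - self.sys.pos[pairs[:, 0]]
            box = self.sys.domain
            for ax in range(2):
                if self.sys.periodic_axes[ax]:
                    d[:, ax] -= box[ax] * np.round(d[:, ax] / box[ax])
            sep = (np.linalg.norm(d, axis=1)
                   - self.sys.radius[pairs[:, 0]]
                   - self.sys.radius[pairs[:, 1]])
            bonded = pairs[sep < self.cfg.bond_gap]
        else:
            bonded = pairs
        adj = sp.coo_matrix((np.ones(len(bonded)),
                             (bonded[:, 0], bonded[:, 1])), shape=(n, n))
        _, labels = csgraph.connected_components(adj, directed=False)
        return labels

    def _detect_detachment(self):
        labels = self._bond_components()
        wall = self.sys.types == int(ParticleType.WALL)
        wall_labels = np.unique(labels[wall])
        attached = np.isin(labels, wall_labels)
        self.attached = attached | wall
        vols = self.sys.volumes()
        det = ~self.attached & self.sys.mobile
        if det.any():
            for lab in np.unique(labels[det]):
                members = np.where((labels == lab) & det)[0]
                new = set(int(i) for i in self.sys.ids[members]) \
                    - self._detached_ids
                if not new:
                    continue
                sel = np.isin(self.sys.ids[members], list(new))
                vol = float(vols[members][sel].sum())
                self.events.append(DetachmentEvent(
                    time=self.t, particle_ids=frozenset(new), volume=vol))
                self._detached_ids |= new

    def _sample_stress_strain(self):
        try:
            alpha = analysis.shear_strain(self.sys, self.reference,
                                          planes=self.planes,
                                          mask=self.attached)
        except ValueError:
            return
        live = self.sys.mobile & self.attached
        kin = float((self.sys.mass[live] * self.sys.vel[live, 0]
                     * self.sys.vel[live, 2]).sum())
        # the raw pair virial is a pressure-convention sum (compression
        # positive); the recorded sigma_xz is the transmitted shear
        # stress, positive under forward (flow-direction) loading
        sigma = -(self._pair_w_xz + kin) / self.V_biofilm
        self.records.append(StressStrainRecord(
            t=self.t, sigma_xz=sigma, alpha=alpha))

    PURGE_DISTANCE = 5.0e-6  # m: debris farther than this from the
    # attached colony is removed (it has left the biofilm's neighborhood;
    # with cyclic boundaries it would otherwise re-enter and bombard the
    # colony, which a channel with an outlet does not do)

    def _purge_debris(self):
        """Remove detached particles that drifted away from the colony.

        In inlet mode particles past the outlet are removed as well.
        Detachment statistics are unaffected: events are recorded when a
        cluster first loses wall connectivity, before any purge.
        """
        from scipy.spatial import cKDTree

        gone = np.zeros(self.sys.n, dtype=bool)
        if self.cfg.drive == "inlet":
            gone |= (self.sys.pos[:, 0] > self.sys.domain[0]) & self.sys.mobile
        debris = self.sys.mobile & ~self.attached & ~gone
        anchor = self.sys.mobile & self.attached
        if debris.any() and anchor.any():
            box = self.sys.domain
            boxsize = [box[0] if self.sys.periodic_axes[0] else 1e9,
                       box[1], 1e9]
            apts = self.sys.pos[anchor].copy()
            dpts = self.sys.pos[debris].copy()
            for p in (apts, dpts):
                for ax in (0, 1):
                    if self.sys.periodic_axes[ax]:
                        p[:, ax] %= box[ax]
                np.clip(p, 0.0, None, out=p)
            tree = cKDTree(apts, boxsize=boxsize)
            dist, _ = tree.query(dpts)
            far = np.where(debris)[0][dist > self.PURGE_DISTANCE]
            gone[far] = True
        if gone.any():
            keep = ~gone
            self.sys = self.sys.select(keep)
            self.attached = self.attached[keep]
            self.neighbors = dem.NeighborState(
                self.sys, self.list_cutoff,
                pair_cutoff_factor=self.cfg.cohesion_cutoff_factor,
                skin=self.skin)
            self._pairdat = dem.build_pair_data(
                self.sys, self.neighbors.pairs, self.cfg.cohesion,
                self.cfg.cohesion_cutoff_factor)
            self._pos_at_rebuild = self.sys.pos.copy()

    # -- main loop ---------------------------------------------------------
    def advance(self, duration: float):
        cfg = self.cfg
        n_fluid = int(round(duration / cfg.dt_fluid))
        box = self.sys.domain
        perx = self.sys.periodic_axes[0]
        cp = cfg.contact
        for _ in range(n_fluid):
            U = 0.0 if self._settling else cfg.boundary_speed(self.t)
            relaxing = cfg.mode == "ramp" and self.t > cfg.t_load \
                and not self._settling
            bc = BoundaryConditions(self.grid.mode, U=U)

            forces, drag_c, u_f = coupling.particle_fluid_forces(
                self.sys, self.grid)
            lift_part = forces - drag_c[:, None] * (u_f - self.sys.vel)
            coupling.eulerian_fields(self.sys, self.grid,
                                     fluid_forces=lift_part, drag_c=drag_c)
            if cfg.freeze_fluid and relaxing:
                self.grid.u[:] = 0.0
                self.grid.v[:] = 0.0
                self.grid.w[:] = 0.0
                forces[:] = 0.0
                drag_c[:] = 0.0
                u_f[:] = 0.0
            else:
                step_fluid(self.grid, cfg.dt_fluid, bc)

            lift = lift_part
            if not np.all(np.isfinite(self.sys.vel)):
                raise RuntimeError(
                    f"numerical blow-up at t = {self.t * 1e3:.3f} ms")
            self._pair_w_xz = dem._run_substeps(
                self.sys.pos, self.sys.vel, self.sys.force, self.sys.radius,
                self.sys.mass, self.sys.mobile, self.neighbors.pairs,
                self.neighbors.shear, self._pairdat, cp.k_n, cp.k_t,
                cp.gamma_n, cp.gamma_t, cfg.cohesion.s_min,
                box, perx, self.sys.periodic_axes[1], drag_c, u_f, lift,
                cfg.substeps, cfg.dt_dem,
                self.attached.astype(np.uint8))
            self.t += cfg.dt_fluid
            self._step_count += 1
            if self._step_count % self.sample_every == 0:
                self._sample_stress_strain()
            if self._step_count % self.detect_every == 0:
                self._detect_detachment()
                self._purge_debris()
            disp = self.sys.pos - self._pos_at_rebuild
            for ax in range(2):
                if self.sys.periodic_axes[ax]:
                    disp[:, ax] -= box[ax] * np.round(disp[:, ax] / box[ax])
            if np.abs(disp).max() > 0.5 * self.skin:
                self.neighbors.rebuild(self.sys)
                self._pairdat = dem.build_pair_data(
                    self.sys, self.neighbors.pairs, cfg.cohesion,
                    cfg.cohesion_cutoff_factor)
                self._pos_at_rebuild = self.sys.pos.copy()
        self._detect_detachment()
        self._sample_stress_strain()


def run_steady_flow(biofilm: ParticleSystem, U: float, duration: float,
                    config: SimulationConfig) -> ExperimentResult:
    """Constant-speed exposure: log detachment, return the rate coefficient
    over the initial window (default 14 ms, capped at the run duration)."""
    if U <= 0:
        raise ValueError("driving speed must be positive")
    cfg = replace(config, mode="steady", U=U)
    run = _CoupledRun(biofilm, cfg)
    run.settle()
    t0_snapshot = run.sys.copy()
    run.advance(duration)
    window = min(cfg.detachment_window, duration)
    coeff = analysis.detachment_rate_coefficient(
        run.events, run.V_particles, window=window)
    result = ExperimentResult(
        snapshots=[(0.0, t0_snapshot), (run.t, run.sys)],
        stress_strain=run.records,
        events=run.events,
        summary={
            "detachment_rate_coefficient": coeff,
            "n_events": len(run.events),
            "n_erosion": sum(1 for e in run.events
                             if e.kind is analysis.DetachmentKind.EROSION),
            "n_sloughing": sum(1 for e in run.events
                               if e.kind is analysis.DetachmentKind.SLOUGHING),
            "detached_fraction": sum(e.volume for e in run.events)
            / run.V_particles,
        },
    )
    return result


def run_deformation_recovery(biofilm: ParticleSystem, a: float,
                             t_load: float = 3.0e-3, t_relax: float = 17.0e-3,
                             config: SimulationConfig | None = None
                             ) -> ExperimentResult:
    """Ramp-load / relax cycle: U(t) = a t for t <= t_load, then 0.

    The summary carries the apparent shear modulus (loading samples with
    strain < 0.1), a single-rate Prony fit, the recovery percentage and
    the hysteresis-loop area.
    """
    if a < 0:
        raise ValueError("acceleration must be non-negative")
    cfg = replace(config or desk_config(), mode="ramp", accel=a,
                  t_load=t_load, t_relax=t_relax)
    run = _CoupledRun(biofilm, cfg, sample_every=5)
    run.settle()
    t0_snapshot = run.sys.copy()
    run.advance(t_load + t_relax)
    t, s_raw, al_raw = ExperimentResult(stress_strain=run.records).trace()
    # when the colony sloughs its front, the measured edge changes body
    # and the raw strain trace jumps discontinuously; cycle-integral
    # observables (dissipation, recovery) only make sense up to that
    # point, so they are evaluated on the trace truncated at the first
    # jump far above the per-step strain scale
    jumps = np.where(np.abs(np.diff(al_raw)) > 0.15)[0]
    cut = int(jumps[0]) + 1 if len(jumps) else len(al_raw)
    # the leading-edge strain estimator has ~0.02 rad of particle-hop
    # jitter; summaries are computed on short-window moving averages
    s = _smooth(s_raw)
    al = _smooth(al_raw)
    t_c = t[:cut]
    s_c = _smooth(s_raw[:cut])
    al_c = _smooth(al_raw[:cut])
    summary: dict = {"peak_velocity": cfg.peak_velocity}
    if len(t) >= 3 and np.any(al > 0):
        load = t <= t_load
        try:
            summary["G_apparent"] = analysis.apparent_shear_modulus(
                (t[load], s[load], al[load]), strain_floor=0.02)
        except ValueError:
            pass
        try:
            fit = analysis.prony_fit((t, s, al))
            summary.update(G_eq=fit.G_eq, eta=fit.eta, prony_tau=fit.tau,
                           prony_residual=fit.residual)
        except (RuntimeError, ValueError):
            pass
        try:
            summary["recovery_percent"] = analysis.recovery_fraction(
                (t_c, s_c, al_c), t_load)
        except ValueError:
            pass
        summary["alpha_peak"] = float(np.interp(t_load, t_c, al_c))
        # dissipated energy density: the path-work integral of sigma
        # over the strain history.  For a cycle whose strain closes this
        # equals the hysteresis-loop polygon area; with residual creep
        # (strain still advancing at low stress after unloading) the
        # polygon self-intersects while the path work stays meaningful.
        summary["hysteresis_area"] = float(np.trapezoid(s_c, al_c))
        summary["sigma_peak"] = float(s.max())
    result = ExperimentResult(
        snapshots=[(0.0, t0_snapshot), (run.t, run.sys)],
        stress_strain=run.records,
        events=run.events,
        summary=summary,
        processed_trace=(t_c, s_c, al_c) if len(t) >= 3 else None,
    )
    return result


#: Desk-scale study conditions: driving speeds for the velocity sweep,
#: EPS yields for the EPS sweep, ramp accelerations for the loading-rate
#: sweep, and the reduced experiment durations.
DESK_VELOCITIES = (0.01, 0.03, 0.1)
DESK_EPS_YIELDS = (0.12, 0.17, 0.22)
DESK_MECH_YIELDS = (0.17, 0.195, 0.22)  # high-EPS colonies for ramps
DESK_ACCELERATIONS = (20.0, 40.0, 80.0)
DESK_STEADY_DURATION = 4.0e-3
DESK_T_LOAD = 1.5e-3
DESK_T_RELAX = 4.0e-3


def desk_steady_summary(Y_eps: float, U: float, seed: int,
                        duration: float = DESK_STEADY_DURATION) -> dict:
    """One desk-scale steady-flow replicate; returns the run summary."""
    biofilm = desk_biofilm(Y_eps=Y_eps, seed=seed)
    res = run_steady_flow(biofilm, U=U, duration=duration,
                          config=desk_config())
    return res.summary


def desk_ramp_experiment(Y_eps: float, a: float, seed: int,
                         t_load: float = DESK_T_LOAD,
                         t_relax: float = DESK_T_RELAX):
    """One desk-scale deformation-recovery replicate.

    Returns (summary, trace) where trace is the (t, sigma, alpha) tuple
    of the smoothed stress-strain record truncated at any front-slough
    discontinuity -- the form the viscoelastic fits consume (e.g. a
    joint Prony fit over several loading rates).
    """
    biofilm = desk_biofilm(Y_eps=Y_eps, seed=seed)
    res = run_deformation_recovery(biofilm, a=a, t_load=t_load,
                                   t_relax=t_relax, config=desk_config())
    return res.summary, res.processed_trace


def desk_ramp_summary(Y_eps: float, a: float, seed: int,
                      t_load: float = DESK_T_LOAD,
                      t_relax: float = DESK_T_RELAX) -> dict:
    """One desk-scale deformation-recovery replicate; returns the summary."""
    return desk_ramp_experiment(Y_eps, a, seed, t_load, t_relax)[0]


def run_replicates(runner, n: int = 3, seeds=None) -> dict:
    """Mean and sample standard deviation of summary metrics across seeds.

    ``runner(seed) -> dict`` executes one replicate.  Returns
    {metric: (mean, sd)} over the metrics present in every replicate.
    """
    if n < 1:
        raise ValueError("need at least one replicate")
    seeds = list(range(n)) if seeds is None else list(seeds)[:n]
    results = [runner(s) for s in seeds]
    keys = set(results[0])
    for r in results[1:]:
        keys &= set(r)
    out = {}
    for k in sorted(keys):
        vals = np.array([float(r[k]) for r in results])
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        out[k] = (float(vals.mean()), sd)
    return out
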