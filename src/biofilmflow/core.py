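"""Domain types, parameter tables and configuration for the biofilm flow model.

All internal quantities are strict SI (m, s, kg, N, Pa, J).  Configuration
files may use micrometre / millisecond convenience keys (``*_um``, ``*_ms``)
which are converted on load; see :func:`load_config`.

The mechanical defaults collected in :data:`TABLE1` are the published
parameter set for the micron-scale agent model: particle density
1e3 kg/m3, Hookean normal/tangential elastic constants 1e3 kg m-1 s-2,
normal damping 1e13 m-1 s-1, tangential damping 10 m-1 s-1, and five
pairwise Hamaker-type cohesive strengths spanning three orders of
magnitude between bacteria-bacteria and EPS-EPS bonds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "ParticleType",
    "Particle",
    "ParticleSystem",
    "ContactParams",
    "CohesionMatrix",
    "FluidProps",
    "SimulationConfig",
    "ConfigError",
    "load_config",
    "save_config",
    "make_cohesion_matrix",
    "particle_mass",
    "TABLE1",
    "PARTICLE_DENSITY",
    "RADIUS_MIN",
    "RADIUS_MAX",
]


class ParticleType(IntEnum):
    """Agent classes: living cells, excreted polymer agents, substratum."""

    BACTERIUM = 0
    EPS = 1
    WALL = 2


PARTICLE_DENSITY = 1.0e3  # kg/m3, all agent classes
RADIUS_MIN = 0.35e-6  # m, living agents (diameters 0.7-1.4 um)
RADIUS_MAX = 0.70e-6  # m

#: Published mechanical parameter set (SI).
TABLE1 = {
    "density": PARTICLE_DENSITY,
    "k_n": 1.0e3,  # kg m-1 s-2
    "k_t": 1.0e3,
    "gamma_n": 1.0e13,  # m-1 s-1
    "gamma_t": 10.0,
    "cohesion": {
        ("BACTERIUM", "EPS"): 1.6e-18,  # J
        ("BACTERIUM", "WALL"): 2.3e-21,
        ("EPS", "WALL"): 2.3e-18,
        ("EPS", "EPS"): 5.0e-18,
        ("BACTERIUM", "BACTERIUM"): 1.6e-21,
        ("WALL", "WALL"): 0.0,
    },
    "rho_f": 1.0e3,  # kg/m3
    "mu": 1.0e-3,  # kg m-1 s-1
}


def particle_mass(radius: float | np.ndarray, density: float = PARTICLE_DENSITY):
    """Sphere mass at the model density."""
    return density * (4.0 / 3.0) * math.pi * np.asarray(radius) ** 3


class ConfigError(ValueError):
    """Raised when a configuration violates a documented invariant."""


@dataclass(frozen=True)
class Particle:
    """A single bacterium, EPS agent or wall particle (SI units)."""

    id: int
    ptype: ParticleType
    position: np.ndarray
    velocity: np.ndarray
    radius: float
    mass: float
    force: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, float))
        object.__setattr__(self, "velocity", np.asarray(self.velocity, float))
        object.__setattr__(self, "force", np.asarray(self.force, float))

    @property
    def volume(self) -> float:
        return (4.0 / 3.0) * math.pi * self.radius**3

    @staticmethod
    def make(pid, ptype, position, radius, velocity=(0.0, 0.0, 0.0)):
        ptype = ParticleType(ptype)
        vel = np.zeros(3) if ptype is ParticleType.WALL else np.asarray(velocity, float)
        return Particle(pid, ptype, np.asarray(position, float), vel, float(radius),
                        float(particle_mass(radius)))


class ParticleSystem:
    """All particles plus domain geometry; the Lagrangian state.

    Structure-of-arrays container: ``pos``/``vel``/``force`` are (N, 3)
    float arrays, ``radius``/``mass`` are (N,) and ``types`` is an (N,)
    int8 array of :class:`ParticleType` values.  The domain is a box
    ``[0, L] x [0, W] x [0, H]`` with cyclic x/y boundaries, a substratum
    (wall particle layer) at z ~ 0 and a driven lid at z = H.
    """

    def __init__(self, domain, periodic_axes=(True, True, False), wall_z0=0.0):
        self.domain = np.asarray(domain, float)
        if self.domain.shape != (3,) or np.any(self.domain <= 0):
            raise ConfigError("domain must be three positive extents")
        self.periodic_axes = tuple(bool(b) for b in periodic_axes)
        self.wall_z0 = float(wall_z0)
        self.ids = np.empty(0, dtype=np.int64)
        self.types = np.empty(0, dtype=np.int8)
        self.pos = np.empty((0, 3))
        self.vel = np.empty((0, 3))
        self.force = np.empty((0, 3))
        self.radius = np.empty(0)
        self.mass = np.empty(0)
        self._next_id = 0

    # -- construction -----------------------------------------------------
    def add(self, ptype, position, radius, velocity=(0.0, 0.0, 0.0)) -> int:
        pid = self._next_id
        self._next_id += 1
        ptype = ParticleType(ptype)
        vel = (0.0, 0.0, 0.0) if ptype is ParticleType.WALL else velocity
        self.ids = np.append(self.ids, pid)
        self.types = np.append(self.types, np.int8(ptype))
        self.pos = np.vstack([self.pos, np.asarray(position, float)])
        self.vel = np.vstack([self.vel, np.asarray(vel, float)])
        self.force = np.vstack([self.force, np.zeros(3)])
        self.radius = np.append(self.radius, float(radius))
        self.mass = np.append(self.mass, float(particle_mass(radius)))
        return pid

    @classmethod
    def from_particles(cls, particles: Iterable[Particle], domain,
                       periodic_axes=(True, True, False), wall_z0=0.0):
        sys_ = cls(domain, periodic_axes, wall_z0)
        plist = list(particles)
        n = len(plist)
        sys_.ids = np.array([p.id for p in plist], dtype=np.int64)
        sys_.types = np.array([int(p.ptype) for p in plist], dtype=np.int8)
        sys_.pos = np.array([p.position for p in plist], float).reshape(n, 3)
        sys_.vel = np.array([p.velocity for p in plist], float).reshape(n, 3)
        sys_.force = np.zeros((n, 3))
        sys_.radius = np.array([p.radius for p in plist], float)
        sys_.mass = np.array([p.mass for p in plist], float)
        sys_._next_id = int(sys_.ids.max()) + 1 if n else 0
        return sys_

    # -- queries -----------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.ids)

    def particle(self, i: int) -> Particle:
        return Particle(int(self.ids[i]), ParticleType(int(self.types[i])),
                        self.pos[i].copy(), self.vel[i].copy(),
                        float(self.radius[i]), float(self.mass[i]),
                        self.force[i].copy())

    def volumes(self) -> np.ndarray:
        return (4.0 / 3.0) * math.pi * self.radius**3

    def mask(self, ptype: ParticleType) -> np.ndarray:
        return self.types == int(ptype)

    @property
    def mobile(self) -> np.ndarray:
        return self.types != int(ParticleType.WALL)

    def copy(self) -> "ParticleSystem":
        out = ParticleSystem(self.domain.copy(), self.periodic_axes, self.wall_z0)
        for name in ("ids", "types", "pos", "vel", "force", "radius", "mass"):
            setattr(out, name, getattr(self, name).copy())
        out._next_id = self._next_id
        return out

    def select(self, keep: np.ndarray) -> "ParticleSystem":
        """New system containing only particles where ``keep`` is True."""
        out = ParticleSystem(self.domain.copy(), self.periodic_axes, self.wall_z0)
        for name in ("ids", "types", "pos", "vel", "force", "radius", "mass"):
            setattr(out, name, getattr(self, name)[keep].copy())
        out._next_id = self._next_id
        return out

    def wrap(self) -> None:
        """Apply periodic wrapping along the cyclic axes in place."""
        for ax in range(3):
            if self.periodic_axes[ax]:
                self.pos[:, ax] %= self.domain[ax]


@dataclass(frozen=True)
class ContactParams:
    """Hookean spring-dashpot contact constants (SI, see module docstring)."""

    k_n: float = TABLE1["k_n"]
    k_t: float = TABLE1["k_t"]
    gamma_n: float = TABLE1["gamma_n"]
    gamma_t: float = TABLE1["gamma_t"]

    def __post_init__(self):
        for name in ("k_n", "k_t", "gamma_n", "gamma_t"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")


def _pair_key(a, b):
    ta = a if isinstance(a, str) else ParticleType(a).name
    tb = b if isinstance(b, str) else ParticleType(b).name
    if ta not in ParticleType.__members__ or tb not in ParticleType.__members__:
        raise ConfigError(f"unknown particle type pair ({a}, {b})")
    return tuple(sorted((ta, tb)))


class CohesionMatrix:
    """Symmetric pairwise cohesive strengths A (J) plus the minimum
    separation ``s_min`` (m) at which the sphere-sphere attraction is
    clamped when surfaces touch."""

    def __init__(self, table: np.ndarray, s_min: float = 1.0e-9):
        table = np.asarray(table, float)
        if table.shape != (3, 3) or not np.array_equal(table, table.T):
            raise ConfigError("cohesion table must be symmetric 3x3")
        if np.any(table < 0):
            raise ConfigError("cohesive strengths must be non-negative")
        if s_min <= 0:
            raise ConfigError("s_min must be positive")
        self.table = table
        self.s_min = float(s_min)

    def lookup(self, a, b) -> float:
        return float(self.table[int(ParticleType(a) if not isinstance(a, str)
                                    else ParticleType[a]),
                                int(ParticleType(b) if not isinstance(b, str)
                                    else ParticleType[b])])

    def scaled(self, factor: float) -> "CohesionMatrix":
        """All strengths multiplied by ``factor`` (ratios preserved)."""
        return CohesionMatrix(self.table * factor, self.s_min)

    def __eq__(self, other):
        return (isinstance(other, CohesionMatrix)
                and np.array_equal(self.table, other.table)
                and self.s_min == other.s_min)

    def __hash__(self):
        return hash((self.table.tobytes(), self.s_min))


def make_cohesion_matrix(overrides: Mapping | None = None,
                         s_min: float = 1.0e-9) -> CohesionMatrix:
    """Build the cohesive-strength lookup, defaulting to the published values.

    ``overrides`` maps type pairs (tuples of :class:`ParticleType` or their
    names, either ordering) to strengths in J.
    """
    entries = {_pair_key(*k): float(v) for k, v in TABLE1["cohesion"].items()}
    for k, v in (overrides or {}).items():
        if not isinstance(k, tuple) or len(k) != 2:
            raise ConfigError(f"cohesion override key must be a type pair: {k!r}")
        if v < 0:
            raise ConfigError("cohesive strength must be non-negative")
        entries[_pair_key(*k)] = float(v)
    table = np.zeros((3, 3))
    for (na, nb), v in entries.items():
        ia, ib = ParticleType[na], ParticleType[nb]
        table[ia, ib] = table[ib, ia] = v
    return CohesionMatrix(table, s_min=s_min)


@dataclass(frozen=True)
class FluidProps:
    """Newtonian carrier-fluid properties (water at the published values)."""

    rho_f: float = TABLE1["rho_f"]
    mu: float = TABLE1["mu"]

    def __post_init__(self):
        if self.rho_f <= 0 or self.mu <= 0:
            raise ConfigError("fluid density and viscosity must be positive")

    @property
    def nu(self) -> float:
        return self.mu / self.rho_f


def _default_dt_dem(k_n: float) -> float:
    m_min = float(particle_mass(RADIUS_MIN))
    return 0.05 * math.sqrt(m_min / k_n)


@dataclass(frozen=True)
class SimulationConfig:
    """Validated experiment configuration (SI units).

    ``mode`` selects the flow protocol: ``steady`` holds the boundary speed
    at ``U``; ``ramp`` accelerates it as ``a * t`` for ``t_load`` seconds and
    then sets it to zero for ``t_relax`` (the deformation-recovery test).
    ``drive`` selects the fluid driving: ``couette`` (moving top lid, cyclic
    streamwise boundaries, the default) or ``inlet`` (prescribed inflow).
    """

    dt_dem: float = 0.0  # 0 -> stability default 0.05*sqrt(m_min/k_n)
    dt_fluid: float = 0.0  # 0 -> 100 * dt_dem
    grid: tuple = (40, 6, 10)
    domain: tuple = (200e-6, 30e-6, 50e-6)
    mode: str = "steady"
    drive: str = "couette"
    U: float = 0.3  # m/s, steady boundary speed
    accel: float = 20.0  # m/s2, ramp mode
    t_load: float = 3.0e-3
    t_relax: float = 17.0e-3
    duration: float = 40.0e-3  # steady mode
    seed: int = 0
    contact: ContactParams = field(default_factory=ContactParams)
    cohesion: CohesionMatrix = field(default_factory=make_cohesion_matrix)
    fluid: FluidProps = field(default_factory=FluidProps)
    cohesion_cutoff_factor: float = 5.0  # s cutoff = factor * min radius
    bond_gap: float = 50.0e-9  # cluster connectivity gap
    freeze_fluid: bool = False  # literal "flow stopped" reading during relax
    detachment_window: float = 14.0e-3

    def __post_init__(self):
        if self.dt_dem == 0.0:
            object.__setattr__(self, "dt_dem", _default_dt_dem(self.contact.k_n))
        if self.dt_fluid == 0.0:
            object.__setattr__(self, "dt_fluid", 100.0 * self.dt_dem)
        if self.dt_dem <= 0 or self.dt_fluid <= 0:
            raise ConfigError("time steps must be positive")
        ratio = self.dt_fluid / self.dt_dem
        if abs(ratio - round(ratio)) > 1e-9 * ratio or round(ratio) < 1:
            raise ConfigError("dt_fluid must be an integer multiple of dt_dem")
        for name in ("t_load", "t_relax", "duration"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.mode not in ("steady", "ramp"):
            raise ConfigError(f"unknown experiment mode {self.mode!r}")
        if self.drive not in ("couette", "inlet"):
            raise ConfigError(f"unknown driving mode {self.drive!r}")
        if self.U < 0 or self.accel < 0:
            raise ConfigError("speeds and accelerations must be non-negative")
        if len(self.grid) != 3 or any(int(g) < 1 for g in self.grid):
            raise ConfigError("grid must be three positive cell counts")
        object.__setattr__(self, "grid", tuple(int(g) for g in self.grid))
        object.__setattr__(self, "domain", tuple(float(x) for x in self.domain))

    @property
    def substeps(self) -> int:
        """DEM sub-steps per fluid step."""
        return int(round(self.dt_fluid / self.dt_dem))

    @property
    def peak_velocity(self) -> float:
        """Boundary speed reached at the end of the loading ramp."""
        return self.accel * self.t_load

    def boundary_speed(self, t: float) -> float:
        """Driving speed U(t) for the configured protocol."""
        if self.mode == "steady":
            return self.U
        return self.accel * t if t <= self.t_load else 0.0


# -- config file I/O -------------------------------------------------------

_UM = 1e-6
_MS = 1e-3
_CONVENIENCE = {  # key suffix -> (canonical name, scale)
    "domain_um": ("domain", _UM),
    "t_load_ms": ("t_load", _MS),
    "t_relax_ms": ("t_relax", _MS),
    "duration_ms": ("duration", _MS),
    "detachment_window_ms": ("detachment_window", _MS),
    "bond_gap_um": ("bond_gap", _UM),
}

_SCALAR_KEYS = {
    "dt_dem", "dt_fluid", "mode", "drive", "U", "accel", "t_load", "t_relax",
    "duration", "seed", "cohesion_cutoff_factor", "bond_gap", "freeze_fluid",
    "detachment_window",
}


def load_config(path) -> SimulationConfig:
    """Read a YAML key-value config; omitted keys take the documented defaults.

    Recognised sections: top-level scalars matching
    :class:`SimulationConfig` fields, ``grid: [nx, ny, nz]``,
    ``domain``/``domain_um``, ``contact: {k_n, k_t, gamma_n, gamma_t}``,
    ``fluid: {rho_f, mu}``, ``cohesion: {"EPS-EPS": 5e-18, ..., s_min: 1e-9}``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping of key: value pairs")
    kw: dict = {}
    for key, (canon, scale) in _CONVENIENCE.items():
        if key in raw:
            v = raw.pop(key)
            kw[canon] = tuple(x * scale for x in v) if isinstance(v, (list, tuple)) \
                else v * scale
    for key in list(raw):
        if key in _SCALAR_KEYS:
            kw[key] = raw.pop(key)
    if "grid" in raw:
        kw["grid"] = tuple(raw.pop("grid"))
    if "domain" in raw:
        kw["domain"] = tuple(raw.pop("domain"))
    if "contact" in raw:
        kw["contact"] = ContactParams(**raw.pop("contact"))
    if "fluid" in raw:
        kw["fluid"] = FluidProps(**raw.pop("fluid"))
    if "cohesion" in raw:
        sec = dict(raw.pop("cohesion"))
        s_min = float(sec.pop("s_min", 1.0e-9))
        scale = float(sec.pop("scale", 1.0))
        overrides = {tuple(k.split("-")): float(v) for k, v in sec.items()}
        kw["cohesion"] = make_cohesion_matrix(overrides, s_min=s_min).scaled(scale)
    if raw:
        raise ConfigError(f"unknown config keys: {sorted(raw)}")
    try:
        return SimulationConfig(**kw)
    except TypeError as exc:  # unexpected kw should surface as ConfigError
        raise ConfigError(str(exc)) from exc


def save_config(cfg: SimulationConfig, path) -> None:
    """Write a config back out as YAML (SI units, round-trips exactly)."""
    data = {
        "dt_dem": cfg.dt_dem, "dt_fluid": cfg.dt_fluid,
        "grid": list(cfg.grid), "domain": list(cfg.domain),
        "mode": cfg.mode, "drive": cfg.drive, "U": cfg.U, "accel": cfg.accel,
        "t_load": cfg.t_load, "t_relax": cfg.t_relax, "duration": cfg.duration,
        "seed": cfg.seed, "cohesion_cutoff_factor": cfg.cohesion_cutoff_factor,
        "bond_gap": cfg.bond_gap, "freeze_fluid": cfg.freeze_fluid,
        "detachment_window": cfg.detachment_window,
        "contact": {"k_n": cfg.contact.k_n, "k_t": cfg.contact.k_t,
                    "gamma_n": cfg.contact.gamma_n, "gamma_t": cfg.contact.gamma_t},
        "fluid": {"rho_f": cfg.fluid.rho_f, "mu": cfg.fluid.mu},
        "cohesion": {
            "s_min": cfg.cohesion.s_min,
            **{f"{ParticleType(i).name}-{ParticleType(j).name}":
               float(cfg.cohesion.table[i, j])
               for i in range(3) for j in range(i, 3)},
        },
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def with_overrides(cfg: SimulationConfig, **kw) -> SimulationConfig:
    """Functional update helper (dataclass ``replace`` that re-validates)."""
    return replace(cfg, **kw)
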