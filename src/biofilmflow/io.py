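"""Snapshot and time-series output.

Particle snapshots use extended XYZ (plain text, one row per particle
with ``id type x y z radius``) and, optionally, legacy ASCII VTK
(polydata points with radius/type arrays for particles; structured
points for the fluid grid) which ParaView and pyvista read directly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import Particle, ParticleSystem, ParticleType
from .fluid import FluidGrid

__all__ = [
    "write_xyz",
    "read_xyz",
    "write_vtk_particles",
    "write_vtk_grid",
    "stress_strain_frame",
    "events_frame",
]


def write_xyz(system: ParticleSystem, path, comment: str = "") -> None:
    """Extended XYZ: header line count, comment with the domain, then
    ``id type x y z radius`` per particle (SI meters)."""
    live = np.arange(system.n)
    lines = [str(system.n)]
    dom = " ".join(f"{x:.9e}" for x in system.domain)
    props = "Properties=id:I:1:species:S:1:pos:R:3:radius:R:1"
    lines.append(f'Lattice="{dom}" {props} {comment}'.strip())
    for i in live:
        t = ParticleType(int(system.types[i])).name
        x, y, z = system.pos[i]
        lines.append(f"{int(system.ids[i])} {t} {x:.9e} {y:.9e} {z:.9e} "
                     f"{system.radius[i]:.9e}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path) -> ParticleSystem:
    """Read a snapshot written by :func:`write_xyz`."""
    text = Path(path).read_text().strip().splitlines()
    n = int(text[0])
    header = text[1]
    dom = header.split('"')[1].split()
    domain = [float(x) for x in dom[:3]]
    particles = []
    for line in text[2:2 + n]:
        pid, tname, x, y, z, r = line.split()
        particles.append(Particle.make(int(pid), ParticleType[tname],
                                       (float(x), float(y), float(z)),
                                       float(r)))
    return ParticleSystem.from_particles(particles, domain)


def write_vtk_particles(system: ParticleSystem, path) -> None:
    """Legacy ASCII VTK polydata of the particle centers with per-point
    radius and type arrays."""
    n = system.n
    out = ["# vtk DataFile Version 3.0", "biofilm particles", "ASCII",
           "DATASET POLYDATA", f"POINTS {n} double"]
    for p in system.pos:
        out.append(f"{p[0]:.9e} {p[1]:.9e} {p[2]:.9e}")
    out.append(f"POINT_DATA {n}")
    out.append("SCALARS radius double 1")
    out.append("LOOKUP_TABLE default")
    out.extend(f"{r:.9e}" for r in system.radius)
    out.append("SCALARS type int 1")
    out.append("LOOKUP_TABLE default")
    out.extend(str(int(t)) for t in system.types)
    Path(path).write_text("\n".join(out) + "\n")


def write_vtk_grid(grid: FluidGrid, path) -> None:
    """Legacy ASCII VTK structured points with cell-centered velocity,
    pressure and solid fraction."""
    nx, ny, nz = grid.nx, grid.ny, grid.nz
    uc = grid.center_velocity()
    out = ["# vtk DataFile Version 3.0", "fluid grid", "ASCII",
           "DATASET STRUCTURED_POINTS",
           f"DIMENSIONS {nx} {ny} {nz}",
           f"ORIGIN {grid.h[0] / 2:.9e} {grid.h[1] / 2:.9e} {grid.h[2] / 2:.9e}",
           f"SPACING {grid.h[0]:.9e} {grid.h[1]:.9e} {grid.h[2]:.9e}",
           f"POINT_DATA {nx * ny * nz}",
           "VECTORS velocity double"]
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                v = uc[i, j, k]
                out.append(f"{v[0]:.9e} {v[1]:.9e} {v[2]:.9e}")
    out.append("SCALARS pressure double 1")
    out.append("LOOKUP_TABLE default")
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                out.append(f"{grid.p[i, j, k]:.9e}")
    out.append("SCALARS eps_s double 1")
    out.append("LOOKUP_TABLE default")
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                out.append(f"{grid.eps_s[i, j, k]:.9e}")
    Path(path).write_text("\n".join(out) + "\n")


def stress_strain_frame(records) -> pd.DataFrame:
    """Stress-strain record list as a tidy DataFrame (t in s)."""
    return pd.DataFrame({
        "t": [r.t for r in records],
        "sigma_xz": [r.sigma_xz for r in records],
        "alpha": [r.alpha for r in records],
    })


def events_frame(events) -> pd.DataFrame:
    """Detachment event log as a DataFrame."""
    return pd.DataFrame({
        "t": [e.time for e in events],
        "size": [e.size for e in events],
        "volume": [e.volume for e in events],
        "kind": [e.kind.value for e in events],
    })
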