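"""Eulerian averaging, drag/lift closures, momentum exchange."""

import math

import numpy as np
import pytest

from biofilmflow.core import FluidProps, Particle, ParticleSystem, ParticleType
from biofilmflow.coupling import (LocalFluidState, drag_force, eulerian_fields,
                                  exchange_step, interpolate_fluid, lift_force,
                                  local_state, particle_fluid_forces)
from biofilmflow.fluid import BoundaryConditions, FluidGrid, step_fluid

PROPS = FluidProps()


def _one_particle_system(domain, pos, r=0.5e-6, v=(0, 0, 0)):
    sys_ = ParticleSystem(domain)
    sys_.add(ParticleType.BACTERIUM, pos, r, velocity=v)
    return sys_


class TestEulerianFields:
    def test_empty_grid_zero_fields(self, small_domain):
        sys_ = ParticleSystem(small_domain)
        grid = FluidGrid((10, 4, 5), small_domain)
        eulerian_fields(sys_, grid)
        assert np.all(grid.eps_s == 0.0)
        assert np.all(grid.U_s == 0.0)

    def test_single_particle_volume_fraction(self, small_domain):
        # particle at a cell center: eps_s integrates to Vp / Vcell
        grid = FluidGrid((10, 4, 5), small_domain)
        center = ((0.5 + 2) * 5e-6, (0.5 + 1) * 5e-6, (0.5 + 2) * 5e-6)
        sys_ = _one_particle_system(small_domain, center)
        eulerian_fields(sys_, grid)
        vp = 4 / 3 * math.pi * (0.5e-6) ** 3
        assert grid.eps_s.sum() * grid.cell_volume() == pytest.approx(vp)
        # smoothing spreads volume but the peak stays at the host cell
        assert grid.eps_s.argmax() == np.ravel_multi_index((2, 1, 2),
                                                           grid.eps_s.shape)

    def test_volume_conservation_random(self, random_system):
        grid = FluidGrid((10, 4, 5), random_system.domain)
        eulerian_fields(random_system, grid)
        assert grid.eps_s.sum() * grid.cell_volume() == pytest.approx(
            random_system.volumes().sum(), rel=1e-12)

    def test_wall_particles_not_averaged(self, small_domain):
        sys_ = ParticleSystem(small_domain)
        sys_.add(ParticleType.WALL, (25e-6, 10e-6, 0.5e-6), 0.5e-6)
        grid = FluidGrid((10, 4, 5), small_domain)
        eulerian_fields(sys_, grid)
        assert np.all(grid.eps_s == 0.0)

    def test_oversized_particle_rejected(self, small_domain):
        sys_ = _one_particle_system(small_domain, (25e-6, 10e-6, 12e-6),
                                    r=4e-6)
        grid = FluidGrid((10, 4, 5), small_domain)  # 5 um cells
        with pytest.raises(ValueError):
            eulerian_fields(sys_, grid)

    def test_constant_field_interpolates_exactly(self, small_domain, rng):
        grid = FluidGrid((10, 4, 5), small_domain)
        grid.u[:] = 0.123
        pts = rng.uniform([1e-6] * 3, np.array(small_domain) - 1e-6, (20, 3))
        U_f, ef, es, om = interpolate_fluid(grid, pts)
        assert np.allclose(U_f[:, 0], 0.123)
        assert np.allclose(ef, 1.0)
        assert np.allclose(om, 0.0)


class TestDragForce:
    def _lf(self, slip, eps_s=0.001, omega=(0, 0, 0)):
        return LocalFluidState(np.asarray(slip, float), 1.0 - eps_s, eps_s,
                               np.asarray(omega, float))

    def test_no_slip_no_force(self):
        p = Particle.make(0, ParticleType.BACTERIUM, (0, 0, 0), 0.5e-6,
                         velocity=(0.01, 0, 0))
        lf = self._lf((0.01, 0, 0))
        assert np.allclose(drag_force(p, lf, PROPS), 0.0)

    def test_dilute_low_re_matches_stokes(self):
        p = Particle.make(0, ParticleType.BACTERIUM, (0, 0, 0), 0.5e-6)
        slip = 1e-5  # particle Re ~ 1e-8
        f = drag_force(p, self._lf((slip, 0, 0)), PROPS)
        stokes = 3 * math.pi * PROPS.mu * 1e-6 * slip
        assert f[0] == pytest.approx(stokes, rel=0.10)
        assert f[1] == f[2] == 0.0

    def test_linear_in_slip_at_low_re(self):
        p = Particle.make(0, ParticleType.BACTERIUM, (0, 0, 0), 0.5e-6)
        f1 = drag_force(p, self._lf((1e-5, 0, 0)), PROPS)
        f2 = drag_force(p, self._lf((2e-5, 0, 0)), PROPS)
        assert f2[0] / f1[0] == pytest.approx(2.0, rel=0.05)

    def test_force_parallel_to_slip(self, rng):
        p = Particle.make(0, ParticleType.EPS, (0, 0, 0), 0.5e-6)
        slip = rng.normal(0, 0.01, 3)
        f = drag_force(p, self._lf(slip, eps_s=0.2), PROPS)
        cos = f @ slip / (np.linalg.norm(f) * np.linalg.norm(slip))
        assert cos == pytest.approx(1.0)

    def test_requires_positive_solid_fraction(self):
        p = Particle.make(0, ParticleType.BACTERIUM, (0, 0, 0), 0.5e-6)
        with pytest.raises(ValueError):
            drag_force(p, self._lf((0.01, 0, 0), eps_s=0.0), PROPS)

    def test_continuous_toward_dilute_limit(self):
        # the eps_s prefactor of the closure cancels: no blow-up or
        # vanishing as the local solid fraction goes to zero
        p = Particle.make(0, ParticleType.BACTERIUM, (0, 0, 0), 0.5e-6)
        f_dense = drag_force(p, self._lf((1e-3, 0, 0), eps_s=0.01), PROPS)
        f_dilute = drag_force(p, self._lf((1e-3, 0, 0), eps_s=1e-6), PROPS)
        assert f_dilute[0] == pytest.approx(f_dense[0], rel=0.05)


class TestLiftForce:
    def test_irrotational_flow_zero_lift(self):
        p = Particle.make(0, ParticleType.BACTERIUM, (0, 0, 0), 0.5e-6)
        lf = LocalFluidState(np.array([0.1, 0, 0]), 1.0, 0.0, np.zeros(3))
        assert np.all(lift_force(p, lf, PROPS) == 0.0)

    def test_matches_direct_formula_evaluation(self):
        # shear flow u = (gamma z, 0, 0): omega = (0, gamma, 0)
        gamma, d, slip = 2000.0, 1e-6, 0.01
        p = Particle.make(0, ParticleType.BACTERIUM, (0, 0, 0), d / 2)
        lf = LocalFluidState(np.array([slip, 0, 0]), 1.0, 0.0,
                             np.array([0.0, gamma, 0.0]))
        f = lift_force(p, lf, PROPS)
        expect = (1.6 * math.sqrt(PROPS.rho_f * PROPS.mu) * d**2
                  * np.cross([slip, 0, 0], [0, gamma, 0]) / math.sqrt(gamma))
        assert np.allclose(f, expect)
        assert expect[2] > 0  # slip along +x in this shear lifts upward

    def test_orthogonal_to_slip_and_vorticity(self, rng):
        p = Particle.make(0, ParticleType.EPS, (0, 0, 0), 0.5e-6)
        slip = rng.normal(0, 0.01, 3)
        om = rng.normal(0, 500.0, 3)
        lf = LocalFluidState(slip, 1.0, 0.0, om)
        f = lift_force(p, lf, PROPS)
        assert abs(f @ slip) < 1e-12 * np.linalg.norm(f) * np.linalg.norm(slip)
        assert abs(f @ om) < 1e-12 * np.linalg.norm(f) * np.linalg.norm(om)


class TestExchange:
    def test_no_particles_leaves_grid_unchanged(self, small_domain):
        sys_ = ParticleSystem(small_domain)
        grid = FluidGrid((10, 4, 5), small_domain)
        grid.u[:] = 0.05
        u0 = grid.u.copy()
        exchange_step(sys_, grid)
        assert np.array_equal(grid.u, u0)
        assert np.all(grid.F_fp == 0.0)

    def test_momentum_bookkeeping_machine_precision(self, random_system):
        grid = FluidGrid((10, 4, 5), random_system.domain)
        grid.u[:] = 0.05
        grid.w[:, :, 1:-1] = 0.01
        _, _, forces = exchange_step(random_system, grid)
        total = forces.sum(axis=0) \
            + (grid.F_fp * grid.cell_volume()).sum(axis=(0, 1, 2))
        scale = np.abs(forces).sum()
        assert np.all(np.abs(total) < 1e-12 * scale)

    def test_settling_particle_reaches_terminal_velocity(self, small_domain):
        # drag balances a constant applied force within 5% of the
        # analytic balance F = C(v) v
        from biofilmflow.coupling import drag_coefficient

        sys_ = _one_particle_system(small_domain, (25e-6, 10e-6, 12e-6))
        grid = FluidGrid((10, 4, 5), small_domain)
        F = 1e-11  # N, applied along x
        m = sys_.mass[0]
        v = 0.0
        dt = 1e-7
        for _ in range(2000):
            c = float(drag_coefficient(1.0, 1e-6, abs(v), PROPS))
            v += dt / m * (F - c * v)
        c_end = float(drag_coefficient(1.0, 1e-6, abs(v), PROPS))
        assert c_end * v == pytest.approx(F, rel=0.05)


class TestLocalState:
    def test_fraction_bounds_enforced(self):
        with pytest.raises(ValueError):
            LocalFluidState(np.zeros(3), 1.2, -0.2, np.zeros(3))

    def test_curl_of_couette_shear(self, small_domain):
        # u = U z / H  ->  omega_y = -du/dz = -U/H... sign: curl_y = du/dz
        grid = FluidGrid((10, 4, 5), small_domain)
        U, Hz = 0.1, small_domain[2]
        zc = (np.arange(5) + 0.5) * Hz / 5
        grid.u[:] = (U * zc / Hz)[None, None, :]
        st = local_state(grid, (25e-6, 10e-6, 12.5e-6))
        # omega = curl u = (0, du/dz, 0) for u = (u(z), 0, 0)
        assert st.omega[1] == pytest.approx(U / Hz, rel=0.05)
        assert st.omega[0] == pytest.approx(0.0, abs=1e-6)
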