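"""Contact and cohesive forces, neighbor search, time integration."""

import math

import numpy as np
import pytest

from biofilmflow.core import (ContactParams, Particle, ParticleSystem,
                              ParticleType, make_cohesion_matrix)
from biofilmflow.dem import (NeighborState, build_neighbor_list,
                             cohesive_force, cohesive_magnitude,
                             contact_force, stability_dt, step_dem)


def _pair(gap, r1=0.5e-6, r2=0.5e-6, v1=(0, 0, 0), v2=(0, 0, 0)):
    """Two particles along x with surface separation ``gap``."""
    p1 = Particle.make(0, ParticleType.BACTERIUM, (0.0, 0.0, 0.0), r1,
                      velocity=v1)
    p2 = Particle.make(1, ParticleType.BACTERIUM,
                      (r1 + r2 + gap, 0.0, 0.0), r2, velocity=v2)
    return p1, p2


class TestContactForce:
    def test_no_overlap_no_force(self):
        p1, p2 = _pair(gap=10e-9)
        f = contact_force(p1, p2, ContactParams())
        assert np.all(f.f_on_i == 0.0)

    def test_static_overlap_hookean_magnitude(self):
        delta = 10e-9
        p1, p2 = _pair(gap=-delta)
        f = contact_force(p1, p2, ContactParams(k_n=1e3, gamma_n=0.0))
        # repulsive spring k_n * delta along -x (pushes i away from j)
        assert f.f_on_i[0] == pytest.approx(-1e3 * delta)
        assert np.linalg.norm(f.f_on_i) == pytest.approx(1e-5)

    def test_newtons_third_law(self):
        p1, p2 = _pair(gap=-20e-9, v1=(0.01, 0.002, 0), v2=(-0.01, 0, 0.001))
        f = contact_force(p1, p2, ContactParams())
        assert np.allclose(f.f_on_j, -f.f_on_i)

    def test_normal_dashpot_opposes_approach(self):
        p1, p2 = _pair(gap=-10e-9, v1=(0.01, 0, 0))  # i moving toward j
        f_damped = contact_force(p1, p2, ContactParams(gamma_n=1e13))
        f_elastic = contact_force(p1, p2, ContactParams(gamma_n=0.0))
        assert f_damped.f_on_i[0] < f_elastic.f_on_i[0]  # extra push-back

    def test_coincident_centers_error(self):
        p1 = Particle.make(0, ParticleType.EPS, (0, 0, 0), 0.5e-6)
        p2 = Particle.make(1, ParticleType.EPS, (0, 0, 0), 0.5e-6)
        with pytest.raises(ValueError):
            contact_force(p1, p2, ContactParams())


class TestCohesiveForce:
    def test_hamaker_close_range_limit(self):
        # equal spheres at close approach: |F| -> A r / (12 s^2).
        # The exact equal-sphere form is (A/6r) 64 / [u^2 (u+4)^2 (u+2)^3]
        # with u = s/r, so the ratio to the limit is 128/[(u+4)^2 (u+2)^3]:
        # within 1% once u <~ 1/200.
        r, A = 0.5e-6, 5e-18
        for s in (r / 500, r / 1000):
            p1, p2 = _pair(gap=s, r1=r, r2=r)
            f = cohesive_force(p1, p2, A, s_min=1e-12)
            limit = A * r / (12 * s**2)
            assert np.linalg.norm(f.f_on_i) == pytest.approx(limit, rel=0.01)
            assert f.f_on_i[0] > 0  # attractive: i pulled toward j

    def test_matches_exact_equal_sphere_form(self):
        # independent closed form at a moderate separation (s = r/50)
        r, A, s = 0.5e-6, 5e-18, 10e-9
        u = s / r
        exact = (A / (6 * r)) * 64.0 / (u**2 * (u + 4) ** 2 * (u + 2) ** 3)
        p1, p2 = _pair(gap=s, r1=r, r2=r)
        f = cohesive_force(p1, p2, A, s_min=1e-9)
        assert np.linalg.norm(f.f_on_i) == pytest.approx(exact, rel=1e-12)

    def test_far_field_decay(self):
        r, A = 0.5e-6, 5e-18
        near = cohesive_magnitude(10e-9, r, r, A, 1e-9)
        far = cohesive_magnitude(10 * r, r, r, A, 1e-9)
        assert far < 1e-6 * near

    def test_touching_clamps_at_s_min(self):
        r, A, s_min = 0.5e-6, 5e-18, 1e-9
        p1, p2 = _pair(gap=0.0, r1=r, r2=r)
        f0 = cohesive_force(p1, p2, A, s_min=s_min)
        expect = cohesive_magnitude(s_min, r, r, A, s_min)
        assert np.linalg.norm(f0.f_on_i) == pytest.approx(expect)
        # overlapping pair clamps to the same value
        p1o, p2o = _pair(gap=-50e-9, r1=r, r2=r)
        fo = cohesive_force(p1o, p2o, A, s_min=s_min)
        assert np.linalg.norm(fo.f_on_i) == pytest.approx(expect)

    def test_negative_strength_rejected(self):
        p1, p2 = _pair(gap=1e-9)
        with pytest.raises(ValueError):
            cohesive_force(p1, p2, -1e-18)


class TestNeighborList:
    def test_separated_pair_empty(self, small_domain):
        sys_ = ParticleSystem(small_domain)
        sys_.add(ParticleType.BACTERIUM, (5e-6, 10e-6, 10e-6), 0.5e-6)
        sys_.add(ParticleType.BACTERIUM, (20e-6, 10e-6, 10e-6), 0.5e-6)
        assert len(build_neighbor_list(sys_, 2e-6)) == 0

    def test_equilateral_triangle_three_pairs(self, small_domain):
        sys_ = ParticleSystem(small_domain)
        a = 1.5e-6
        pts = [(10e-6, 10e-6, 10e-6), (10e-6 + a, 10e-6, 10e-6),
               (10e-6 + a / 2, 10e-6 + a * math.sqrt(3) / 2, 10e-6)]
        for p in pts:
            sys_.add(ParticleType.EPS, p, 0.5e-6)
        pairs = build_neighbor_list(sys_, 1e-6)
        assert sorted(map(tuple, pairs)) == [(0, 1), (0, 2), (1, 2)]

    def test_matches_brute_force_with_periodic_wrap(self, random_system):
        cutoff = 2.5e-6
        pairs = set(map(tuple, build_neighbor_list(random_system, cutoff)))
        box = random_system.domain
        brute = set()
        n = random_system.n
        for i in range(n):
            for j in range(i + 1, n):
                d = random_system.pos[j] - random_system.pos[i]
                for ax in range(2):
                    d[ax] -= box[ax] * round(d[ax] / box[ax])
                rc = cutoff + random_system.radius[i] + random_system.radius[j]
                if np.linalg.norm(d) < rc:
                    brute.add((i, j))
        assert pairs == brute

    def test_fast_path_matches_generic(self, random_system):
        # the engine's wall-aware search must agree with the generic one
        for i in range(30):
            random_system.add(ParticleType.WALL,
                              ((i % 10 + 0.5) * 5e-6,
                               (i // 10 + 0.5) * 6e-6, 0.5e-6), 0.5e-6)
        cutoff = 2.5e-6
        fast = NeighborState(random_system, cutoff).pairs
        generic = build_neighbor_list(random_system, cutoff,
                                      exclude_wall_wall=True)
        assert np.array_equal(fast, generic)

    def test_cutoff_beyond_half_box_rejected(self, random_system):
        with pytest.raises(ValueError):
            build_neighbor_list(random_system, 11e-6)  # W = 20 um


class TestStepDEM:
    def _free_particle(self, v):
        sys_ = ParticleSystem((100e-6, 100e-6, 100e-6))
        sys_.add(ParticleType.BACTERIUM, (50e-6, 50e-6, 50e-6), 0.5e-6,
                 velocity=v)
        return sys_

    def test_force_free_straight_line(self):
        v = np.array([0.01, -0.005, 0.002])
        sys_ = self._free_particle(v)
        x0 = sys_.pos[0].copy()
        dt, n = 1e-7, 100
        out = step_dem(sys_, dt, n_steps=n)
        assert np.allclose(out.pos[0], x0 + v * n * dt, rtol=1e-12)

    def test_constant_force_ballistic(self):
        sys_ = self._free_particle((0.001, 0, 0))
        m = sys_.mass[0]
        F = np.array([0.0, 0.0, 2e-12])
        x0, v0 = sys_.pos[0].copy(), sys_.vel[0].copy()
        dt, n = 1e-7, 200
        out = step_dem(sys_, dt, force_hook=lambda s: np.tile(F, (s.n, 1)),
                       n_steps=n)
        t = n * dt
        expect = x0 + v0 * t + 0.5 * F / m * t**2
        assert np.allclose(out.pos[0], expect, rtol=1e-6)

    def test_damped_collision_dissipates(self):
        sys_ = ParticleSystem((100e-6, 100e-6, 100e-6))
        sys_.add(ParticleType.BACTERIUM, (49.3e-6, 50e-6, 50e-6), 0.5e-6,
                 velocity=(0.02, 0, 0))
        sys_.add(ParticleType.BACTERIUM, (50.7e-6, 50e-6, 50e-6), 0.5e-6,
                 velocity=(-0.02, 0, 0))
        cp = ContactParams(k_n=1e-3, k_t=1e-3, gamma_n=1e14, gamma_t=10.0)
        dt = stability_dt(sys_, cp)
        rel0 = 0.04
        out = step_dem(sys_, dt, contact=cp, n_steps=4000)
        rel = abs(out.vel[0, 0] - out.vel[1, 0])
        assert rel < rel0

    def test_energy_conservation_without_damping(self):
        # undamped springs + symplectic integration: < 0.1% drift over 1e4 steps
        sys_ = ParticleSystem((100e-6, 100e-6, 100e-6))
        sys_.add(ParticleType.BACTERIUM, (49.1e-6, 50e-6, 50e-6), 0.5e-6,
                 velocity=(0.02, 0, 0))
        sys_.add(ParticleType.BACTERIUM, (50.9e-6, 50e-6, 50e-6), 0.5e-6,
                 velocity=(-0.02, 0, 0))
        cp = ContactParams(k_n=1e-3, k_t=0.0, gamma_n=0.0, gamma_t=0.0)
        dt = stability_dt(sys_, cp)

        def energy(s):
            ke = 0.5 * float((s.mass * (s.vel**2).sum(axis=1)).sum())
            d = np.linalg.norm(s.pos[1] - s.pos[0])
            delta = max(s.radius[0] + s.radius[1] - d, 0.0)
            return ke + 0.5 * cp.k_n * delta**2

        e0 = energy(sys_)
        out = sys_
        for _ in range(10):
            out = step_dem(out, dt, contact=cp, n_steps=1000)
        assert abs(energy(out) - e0) / e0 < 1e-3

    def test_wall_particles_stay_put(self):
        sys_ = ParticleSystem((100e-6, 100e-6, 100e-6))
        sys_.add(ParticleType.WALL, (50e-6, 50e-6, 0.5e-6), 0.5e-6)
        F = np.array([[1e-9, 0, 0]])
        out = step_dem(sys_, 1e-7, force_hook=lambda s: F, n_steps=50)
        assert np.all(out.pos[0] == sys_.pos[0])
        assert np.all(out.vel[0] == 0.0)

    def test_dt_above_stability_bound_rejected(self):
        sys_ = self._free_particle((0, 0, 0))
        cp = ContactParams()
        with pytest.raises(ValueError):
            step_dem(sys_, 1.0, contact=cp)

    def test_internal_forces_sum_to_zero(self, random_system):
        cp = ContactParams(k_n=1e-3, k_t=1e-3, gamma_n=1e13, gamma_t=10.0)
        coh = make_cohesion_matrix().scaled(1e-4)
        dt = stability_dt(random_system, cp)
        out = step_dem(random_system, dt, contact=cp, cohesion=coh, n_steps=1)
        total = out.force.sum(axis=0)
        fmax = np.abs(out.force).max()
        assert np.all(np.abs(total) <= 1e-12 * max(fmax, 1e-30) + 1e-30)
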