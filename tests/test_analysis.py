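"""Cluster statistics, strain/stress observables, viscoelastic fits."""

import math

import numpy as np
import pytest

from biofilmflow.analysis import (DetachmentEvent, DetachmentKind,
                                  apparent_shear_modulus, classify_detachment,
                                  detachment_rate_coefficient, find_clusters,
                                  global_shear_stress, hysteresis_area,
                                  prony_fit, prony_stress, recovery_fraction,
                                  shear_strain)
from biofilmflow.core import ParticleSystem, ParticleType


def _blob(sys_, center, n, rng, spread=1.5e-6, ptype=ParticleType.BACTERIUM):
    for _ in range(n):
        sys_.add(ptype, np.asarray(center) + rng.normal(0, spread, 3), 0.5e-6)


class TestClusters:
    def test_attached_and_detached_blobs(self, small_domain, rng):
        sys_ = ParticleSystem(small_domain)
        sys_.add(ParticleType.WALL, (10e-6, 10e-6, 0.5e-6), 0.5e-6)
        # blob touching the wall particle
        sys_.add(ParticleType.BACTERIUM, (10e-6, 10e-6, 1.5e-6), 0.5e-6)
        sys_.add(ParticleType.BACTERIUM, (10e-6, 10e-6, 2.5e-6), 0.5e-6)
        # well-separated floating blob
        sys_.add(ParticleType.EPS, (30e-6, 10e-6, 12e-6), 0.5e-6)
        sys_.add(ParticleType.EPS, (30e-6, 10e-6, 13e-6), 0.5e-6)
        clusters = find_clusters(sys_, bond_gap=50e-9)
        assert len(clusters) == 2
        flags = sorted(c.attached for c in clusters)
        assert flags == [False, True]

    def test_chain_is_single_cluster(self, small_domain):
        sys_ = ParticleSystem(small_domain)
        for k in range(10):
            sys_.add(ParticleType.EPS, (10e-6 + k * 1.02e-6, 10e-6, 10e-6),
                     0.5e-6)
        clusters = find_clusters(sys_, bond_gap=50e-9)
        assert len(clusters) == 1 and clusters[0].size == 10

    def test_matches_brute_force_union_find(self, small_domain, rng):
        sys_ = ParticleSystem(small_domain)
        for _ in range(100):
            sys_.add(ParticleType.BACTERIUM,
                     rng.uniform([2e-6] * 3, np.array(small_domain) - 2e-6),
                     rng.uniform(0.35e-6, 0.7e-6))
        gap = 0.4e-6
        got = {frozenset(c.particle_ids) for c in find_clusters(sys_, gap)}
        # brute force union-find over all pairs
        parent = list(range(sys_.n))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        box = sys_.domain
        for i in range(sys_.n):
            for j in range(i + 1, sys_.n):
                d = sys_.pos[j] - sys_.pos[i]
                for ax in range(2):
                    d[ax] -= box[ax] * round(d[ax] / box[ax])
                if (np.linalg.norm(d) - sys_.radius[i] - sys_.radius[j]) < gap:
                    parent[find(i)] = find(j)
        groups = {}
        for i in range(sys_.n):
            groups.setdefault(find(i), set()).add(int(sys_.ids[i]))
        assert got == {frozenset(g) for g in groups.values()}

    def test_bad_gap_rejected(self, small_domain):
        with pytest.raises(ValueError):
            find_clusters(ParticleSystem(small_domain), 0.0)


class TestDetachmentClassification:
    @pytest.mark.parametrize("size, kind", [
        (1, DetachmentKind.EROSION),
        (999, DetachmentKind.EROSION),
        (1000, DetachmentKind.SLOUGHING),
        (5000, DetachmentKind.SLOUGHING),
    ])
    def test_threshold(self, size, kind):
        assert classify_detachment(size) is kind

    def test_invalid_size(self):
        with pytest.raises(ValueError):
            classify_detachment(0)


class TestDetachmentRate:
    def _ev(self, t, vol):
        return DetachmentEvent(time=t, particle_ids=frozenset([id(object())]),
                               volume=vol)

    def test_no_events_zero(self):
        assert detachment_rate_coefficient([], 1e-15) == 0.0

    def test_half_volume_in_window(self):
        ev = self._ev(5e-3, 0.5e-15)
        c = detachment_rate_coefficient([ev], 1e-15, window=14e-3)
        assert c == pytest.approx(0.5 / 14.0)

    def test_event_outside_window_ignored(self):
        ev = self._ev(20e-3, 0.5e-15)
        assert detachment_rate_coefficient([ev], 1e-15, window=14e-3) == 0.0

    def test_monotone_under_added_events(self, rng):
        events = [self._ev(rng.uniform(0, 14e-3), rng.uniform(0, 1e-16))
                  for _ in range(10)]
        V = 1e-14
        cs = [detachment_rate_coefficient(events[:k], V)
              for k in range(len(events) + 1)]
        assert all(b >= a for a, b in zip(cs, cs[1:]))
        assert all(0 <= c <= 1 / 14.0 for c in cs)


def _block_system(domain, nx=6, nz=8, x0=10e-6, y=None, r=0.5e-6):
    """A rectangular wall of particles with a vertical leading edge.

    z layers sit at the centers of the 1 um measurement bins so the
    leading-edge extraction is free of binning aliasing.
    """
    sys_ = ParticleSystem(domain)
    ys = [domain[1] / 6, domain[1] / 2, 5 * domain[1] / 6] if y is None else [y]
    for yy in ys:
        for i in range(nx):
            for k in range(nz):
                sys_.add(ParticleType.BACTERIUM,
                         (x0 + i * 1.05e-6, yy, (k + 0.5) * 1.0e-6), r)
    return sys_


class TestShearStrain:
    def test_identity_zero(self, small_domain):
        ref = _block_system(small_domain)
        assert shear_strain(ref, ref) == pytest.approx(0.0, abs=1e-12)

    def test_affine_shear_recovered(self, small_domain):
        ref = _block_system(small_domain)
        gamma = 0.1
        cur = ref.copy()
        cur.pos[:, 0] += gamma * cur.pos[:, 2]
        assert shear_strain(cur, ref) == pytest.approx(math.atan(gamma),
                                                       rel=1e-3)

    def test_rigid_translation_invariant(self, small_domain):
        ref = _block_system(small_domain)
        cur = ref.copy()
        cur.pos[:, 0] += 3e-6
        assert shear_strain(cur, ref) == pytest.approx(0.0, abs=1e-12)

    def test_empty_planes_error(self, small_domain):
        ref = _block_system(small_domain)
        with pytest.raises(ValueError):
            shear_strain(ref, ref, planes=(19.9e-6,), half_width=1e-8)


class TestGlobalShearStress:
    def test_static_noninteracting_zero(self, small_domain):
        sys_ = _block_system(small_domain)
        sys_.pos[:, 0] *= 3.0  # spread out: no contacts, no cohesion passed
        assert global_shear_stress(sys_, 1e-15) == 0.0

    def test_single_pair_virial_arithmetic(self):
        # branch (1e-6, 0, 0), force on j (0, 0, 1e-9), V = 1e-16
        # sigma = r_x f_z / V = 1e-15 / 1e-16 = 10 Pa
        w_xz = 1e-6 * 1e-9
        sys_ = ParticleSystem((50e-6, 20e-6, 25e-6))
        sys_.add(ParticleType.BACTERIUM, (10e-6, 10e-6, 10e-6), 0.5e-6)
        assert global_shear_stress(sys_, 1e-16, pair_virial_xz=w_xz,
                                   include_kinetic=False) == pytest.approx(10.0)

    def test_kinetic_term(self, small_domain):
        sys_ = ParticleSystem(small_domain)
        sys_.add(ParticleType.BACTERIUM, (10e-6, 10e-6, 10e-6), 0.5e-6,
                 velocity=(0.01, 0.0, 0.002))
        m = sys_.mass[0]
        V = 1e-16
        expect = m * 0.01 * 0.002 / V
        assert global_shear_stress(sys_, V) == pytest.approx(expect)

    def test_invalid_volume(self, small_domain):
        with pytest.raises(ValueError):
            global_shear_stress(ParticleSystem(small_domain), 0.0)


class TestApparentModulus:
    def test_exact_linear_record(self):
        a = np.linspace(1e-3, 0.09, 20)
        assert apparent_shear_modulus((a * 0.0, 10.0 * a, a)) \
            == pytest.approx(10.0)

    def test_strain_cap_excludes_large_strain(self):
        a = np.linspace(1e-3, 0.5, 100)
        s = np.where(a < 0.1, 10.0 * a, 10.0 * a + 100.0)
        assert apparent_shear_modulus((a * 0.0, s, a)) == pytest.approx(10.0)

    def test_noisy_slope_recovered(self, rng):
        a = np.linspace(1e-3, 0.09, 200)
        noise = rng.normal(0, 0.05, a.size)
        s = 7.5 * a + noise * a.std()
        g = apparent_shear_modulus((a * 0.0, s, a))
        se = 2 * noise.std() * a.std() / math.sqrt(a.size) / (a @ a / a.size)
        assert abs(g - 7.5) < se

    def test_no_qualifying_samples(self):
        a = np.array([0.2, 0.3])
        with pytest.raises(ValueError):
            apparent_shear_modulus((a * 0.0, a, a))


class TestPronyFit:
    def _ramp_trace(self, G_eq, G1, tau, rate, t_load, t_end, n=400):
        """Closed-form stress of a ramp-and-hold strain history."""
        t = np.linspace(1e-6, t_end, n)
        alpha = np.where(t <= t_load, rate * t, rate * t_load)
        sigma = np.where(
            t <= t_load,
            rate * (G_eq * t + G1 * tau * (1 - np.exp(-t / tau))),
            rate * (G_eq * t_load + G1 * tau
                    * np.exp(-(t - t_load) / tau)
                    * (1 - np.exp(-t_load / tau))))
        return t, sigma, alpha

    def test_recovers_forward_model_across_seeds(self, rng):
        # G_eq = 4 Pa, eta = G1 tau ~ 8 mPa s: parameters within 10%
        G_eq, G1, tau = 4.0, 11.0, 8.0e-3 / 11.0
        failures = 0
        for _ in range(20):
            traces = []
            for rate in (50.0, 100.0):
                t, s, a = self._ramp_trace(G_eq, G1, tau, rate, 3e-3, 20e-3)
                s = s * (1.0 + rng.normal(0, 0.01, s.size))
                traces.append((t, s, a))
            fit = prony_fit(traces)
            ok = (abs(fit.G_eq - G_eq) / G_eq < 0.10
                  and abs(fit.eta - G1 * tau) / (G1 * tau) < 0.10)
            failures += not ok
        assert failures == 0

    def test_elastic_limit(self):
        t = np.linspace(1e-6, 10e-3, 200)
        alpha = 100.0 * t
        sigma = 12.0 * alpha  # purely elastic, G = 12 Pa
        fit = prony_fit((t, sigma, alpha))
        assert fit.G_eq + fit.G1 * math.exp(0.0) * 0 + 0 == fit.G_eq
        assert fit.G_eq == pytest.approx(12.0, rel=0.05) \
            or fit.G_eq + fit.G1 == pytest.approx(12.0, rel=0.05)

    def test_hereditary_integral_matches_closed_form(self):
        G_eq, G1, tau, rate = 4.0, 11.0, 1e-3, 100.0
        t = np.linspace(1e-6, 3e-3, 600)
        alpha = rate * t
        num = prony_stress(t, alpha, G_eq, G1, tau)
        exact = rate * (G_eq * t + G1 * tau * (1 - np.exp(-t / tau)))
        assert np.allclose(num, exact, rtol=2e-3, atol=1e-4 * exact.max())


class TestRecoveryAndHysteresis:
    def test_full_recovery_100_percent(self):
        t = np.linspace(0, 20e-3, 100)
        alpha = np.where(t <= 3e-3, t / 3e-3, (1 - (t - 3e-3) / 17e-3))
        alpha[-1] = 0.0
        assert recovery_fraction((t, alpha * 0.0, alpha), 3e-3) \
            == pytest.approx(100.0)

    def test_no_relaxation_0_percent(self):
        t = np.linspace(0, 20e-3, 201)  # grid contains t_load exactly
        alpha = np.minimum(t / 3e-3, 1.0)
        assert recovery_fraction((t, alpha * 0.0, alpha), 3e-3) \
            == pytest.approx(0.0, abs=1e-9)

    def test_trace_must_extend_past_loading(self):
        t = np.linspace(0, 2e-3, 10)
        with pytest.raises(ValueError):
            recovery_fraction((t, t, t), 3e-3)

    def test_elastic_loop_zero_area(self):
        a = np.concatenate([np.linspace(0, 1, 20), np.linspace(1, 0, 20)])
        s = 5.0 * a
        assert hysteresis_area(np.column_stack([a, s])) \
            == pytest.approx(0.0, abs=1e-12)

    def test_unit_square_load_unload(self):
        # stress up at zero strain, strain out at high stress, stress
        # down, strain back at low stress: encloses unit area, positive
        loop = [(0, 0), (0, 1), (1, 1), (1, 0)]
        assert hysteresis_area(loop) == pytest.approx(1.0)

    def test_dissipative_orientation_positive(self):
        # loading path above the unloading path -> positive area
        a_up = np.linspace(0, 0.5, 50)
        s_up = 20 * a_up
        a_dn = np.linspace(0.5, 0.1, 50)
        s_dn = 20 * (a_dn - 0.1) * 0.8
        loop = np.column_stack([np.concatenate([a_up, a_dn]),
                                np.concatenate([s_up, s_dn])])
        assert hysteresis_area(loop) > 0.0

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            hysteresis_area([(0, 0), (1, 1)])
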