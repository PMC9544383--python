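"""Shared fixtures: small particle assemblies and cached desk-scale runs.

The coupled-flow experiments are the expensive part of the suite; they
are grown/run once per session and shared between the trend tests and
the acceptance checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from biofilmflow.core import ParticleSystem, ParticleType
from biofilmflow.protocols import desk_biofilm


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_domain():
    return (50e-6, 20e-6, 25e-6)


@pytest.fixture()
def random_system(rng, small_domain):
    """200 random non-wall particles in the desk channel."""
    sys_ = ParticleSystem(small_domain)
    lo = np.full(3, 2e-6)
    hi = np.asarray(small_domain) - 2e-6
    for _ in range(200):
        sys_.add(ParticleType.BACTERIUM, rng.uniform(lo, hi),
                 rng.uniform(0.35e-6, 0.7e-6), velocity=rng.normal(0, 0.01, 3))
    return sys_


_BIOFILM_CACHE: dict = {}


@pytest.fixture(scope="session")
def biofilm_factory():
    """Session-cached desk-scale biofilm colonies keyed by (Y_eps, seed)."""

    def factory(Y_eps: float = 0.18, seed: int = 0, t_grow: float = 3.2e5):
        key = (Y_eps, seed, t_grow)
        if key not in _BIOFILM_CACHE:
            _BIOFILM_CACHE[key] = desk_biofilm(Y_eps=Y_eps, seed=seed,
                                               t_grow=t_grow)
        return _BIOFILM_CACHE[key].copy()

    return factory


_RUN_CACHE: dict = {}


@pytest.fixture(scope="session")
def run_cache():
    """Session-wide memo for expensive coupled runs (keyed by the caller)."""

    def memo(key, fn):
        if key not in _RUN_CACHE:
            _RUN_CACHE[key] = fn()
        return _RUN_CACHE[key]

    return memo
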