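"""Shared fixtures.

Trained agents are expensive, so every test that needs one draws from the
session-scoped caches below; each distinct (task, strategy, seed) is trained
exactly once per session.
"""

import dataclasses

import numpy as np
import pytest

import hexnav as hx


@pytest.fixture(scope="session")
def small_arena():
    return hx.ArenaConfig(side_length=2.0, node_spacing=0.5)


@pytest.fixture(scope="session")
def small_grid(small_arena):
    return hx.build_grid(small_arena)


@pytest.fixture(scope="session")
def default_arena():
    return hx.ArenaConfig()          # 2.75 m, 0.25 m spacing


@pytest.fixture(scope="session")
def default_grid(default_arena):
    return hx.build_grid(default_arena)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


class _TrainCache:
    """Train-once cache keyed by (task, strategy, seed, extras)."""

    def __init__(self):
        self._runs = {}

    def full(self, task, seed):
        key = (task, "full", seed)
        if key not in self._runs:
            cfg = hx.desk_preset(task, "full")
            self._runs[key] = hx.run_full_model(cfg, seed)
        return self._runs[key]

    def generalization(self, task, strategy, seed, **arena_overrides):
        key = (task, strategy, seed, tuple(sorted(arena_overrides.items())))
        if key not in self._runs:
            cfg = hx.desk_preset(task, strategy)
            if arena_overrides:
                cfg = dataclasses.replace(
                    cfg, arena=dataclasses.replace(cfg.arena, **arena_overrides))
            self._runs[key] = hx.run_generalization(cfg, seed)
        return self._runs[key]


@pytest.fixture(scope="session")
def train_cache():
    return _TrainCache()


@pytest.fixture(scope="session")
def guidance_allocentric_agent():
    """One constrained guidance/allocentric agent (larger desk arena,
    full-strength learning, so it reliably converges), with maps and
    classification; reused by the lesion and coverage tests."""
    cfg = hx.desk_generalization_config("guidance", "allocentric")
    out = hx.run_constrained(cfg, seed=7, analyze=True)
    return out
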