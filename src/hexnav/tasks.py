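"""Episodic guidance and aiming tasks on the hex lattice.

Guidance: navigate from a random start to a fixed, unmarked goal node; the
goal is identifiable only through the stable distal landmarks (wall colours,
lights).  Aiming: navigate to a visibly cued goal (red cylinder) that moves
to a new random node every ``cue_relocation_period`` trials.

Rewards follow the shortest-path-encouraging scheme: +1 on reaching the goal,
-1 for every other step (collisions included, the agent stays in place).  A
trial ends on goal arrival or after ``max_steps`` steps, whichever is first;
goal arrival exactly on the last step counts as a success.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .arena import ArenaConfig, GridGraph, Pose, N_HEADINGS, build_grid
from .actions import ActionSpace, apply_action
from .rendering import render

GUIDANCE = "guidance"
AIMING = "aiming"


@dataclass
class EpisodeConfig:
    task: str = GUIDANCE
    max_steps: int = 100
    goal_reward: float = 1.0
    step_reward: float = -1.0
    collision_reward: float = -1.0
    cue_relocation_period: int = 10
    rng_seed: int = 0

    def __post_init__(self):
        if self.task not in (GUIDANCE, AIMING):
            raise ValueError(f"unknown task {self.task!r}")
        if self.max_steps <= 0:
            raise ValueError("max_steps must be positive")


@dataclass
class LocationSplit:
    """Disjoint, exhaustive train/test partition of eligible nodes."""

    train_nodes: np.ndarray
    test_nodes: np.ndarray
    fraction_train: float = 0.8

    def nodes(self, phase: str) -> np.ndarray:
        if phase == "train":
            return self.train_nodes
        if phase == "test":
            return self.test_nodes
        raise ValueError(f"unknown phase {phase!r}")


def make_split(nodes, fraction: float = 0.8, rng_seed: int = 0) -> LocationSplit:
    """Random disjoint partition with ``round(fraction*N)`` training nodes,
    reproducible from the seed."""
    nodes = np.asarray(nodes, dtype=int)
    if len(nodes) < 2:
        raise ValueError("need at least 2 nodes to split")
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(nodes)
    n_train = int(round(fraction * len(nodes)))
    return LocationSplit(np.sort(perm[:n_train]), np.sort(perm[n_train:]), fraction)


def configure_manipulation(base: ArenaConfig, *, arena_size: float | None = None,
                           info_level: str | None = None) -> ArenaConfig:
    """Environmental manipulations: arena-size change, or graded removal of
    spatial information (high = walls + point lights, medium = point lights
    only, low = uniform distant light only)."""
    cfg = base
    if arena_size is not None:
        cfg = replace(cfg, side_length=float(arena_size))
    if info_level is not None:
        if info_level == "high":
            cfg = replace(cfg, walls_present=True, lighting_mode="high")
        elif info_level == "medium":
            cfg = replace(cfg, walls_present=False, lighting_mode="medium")
        elif info_level == "low":
            cfg = replace(cfg, walls_present=False, lighting_mode="low")
        else:
            raise ValueError(f"unknown info_level {info_level!r}")
    if arena_size is None and info_level is None:
        raise ValueError("no manipulation given")
    return cfg


@dataclass
class Transition:
    observation: np.ndarray
    action_index: int
    reward: float
    next_observation: np.ndarray
    terminal: bool


class NavEnv:
    """Episodic environment with a gym-like ``reset``/``step`` surface.

    Observations are rendered lazily and cached per (node, heading, cue)
    triple — the renderer is deterministic, so the cache is exact.
    """

    def __init__(self, arena: ArenaConfig, action_space: ActionSpace,
                 episode: EpisodeConfig, grid: GridGraph | None = None,
                 split: LocationSplit | None = None):
        self.arena = arena
        self.grid = grid if grid is not None else build_grid(arena)
        self.action_space = action_space
        self.cfg = episode
        self.rng = np.random.default_rng(episode.rng_seed)
        all_nodes = np.arange(self.grid.n_nodes)
        self.split = split if split is not None else LocationSplit(all_nodes, np.array([], dtype=int), 1.0)

        if episode.task == GUIDANCE:
            self.goal_node = arena.goal_node if arena.goal_node is not None \
                else self._default_goal()
        else:
            self.goal_node = None      # set per session from the cue
        self.cue_node = None
        self._trials_started = 0
        self._cue_phase = None
        self._obs_cache: dict = {}
        self.pose: Pose | None = None
        self._steps = 0
        self._active = False
        self.last_success = False

    # -- setup -------------------------------------------------------------
    def _default_goal(self) -> int:
        """Fixed unmarked goal: a node in the upper-right quadrant, chosen
        reproducibly from the episode seed."""
        pos = self.grid.positions
        quad = np.flatnonzero((pos[:, 0] > 0) & (pos[:, 1] > 0))
        if len(quad) == 0:
            quad = np.arange(self.grid.n_nodes)
        rng = np.random.default_rng(self.cfg.rng_seed + 1)
        return int(rng.choice(quad))

    @property
    def n_actions(self) -> int:
        return len(self.action_space)

    # -- observations --------------------------------------------------------
    def _observation(self, pose: Pose) -> np.ndarray:
        key = (pose.node, pose.heading, self.cue_node)
        obs = self._obs_cache.get(key)
        if obs is None:
            cue_xy = self.grid.positions[self.cue_node] if self.cue_node is not None else None
            obs = render(self.grid.positions[pose.node], pose.heading,
                         self.arena, cue_xy)
            obs.setflags(write=False)
            self._obs_cache[key] = obs
        return obs

    # -- episode control -----------------------------------------------------
    def reset(self, phase: str = "train", rng: np.random.Generator | None = None):
        """Start a new trial; returns the initial observation.

        Guidance: the start is uniform over the phase's split nodes (redrawn
        if it hits the goal).  Aiming: the cued goal is redrawn from the
        phase's split nodes every ``cue_relocation_period`` trials (and when
        the phase changes); starts are uniform over all nodes.
        """
        rng = rng if rng is not None else self.rng
        if self.cfg.task == AIMING:
            if (self._cue_phase != phase
                    or self._trials_started % self.cfg.cue_relocation_period == 0):
                self.cue_node = int(rng.choice(self.split.nodes(phase)))
                self.goal_node = self.cue_node
                self._cue_phase = phase
            start_pool = np.arange(self.grid.n_nodes)
        else:
            start_pool = self.split.nodes(phase)
        self._trials_started += 1

        node = int(rng.choice(start_pool))
        while node == self.goal_node:
            node = int(rng.choice(start_pool))
        self.pose = Pose(node, int(rng.integers(N_HEADINGS)))
        self._steps = 0
        self._active = True
        self.last_success = False
        return self._observation(self.pose)

    def step(self, action_index: int) -> Transition:
        if not self._active:
            raise RuntimeError("episode finished")
        obs = self._observation(self.pose)
        outcome = apply_action(self.pose, self.action_space[action_index], self.grid)
        self._steps += 1
        self.pose = outcome.new_pose

        if self.pose.node == self.goal_node:
            reward, self.last_success, terminal = self.cfg.goal_reward, True, True
        else:
            reward = self.cfg.collision_reward if outcome.collided else self.cfg.step_reward
            terminal = self._steps >= self.cfg.max_steps
        if terminal:
            self._active = False
        nxt = self._observation(self.pose)
        return Transition(obs, action_index, float(reward), nxt, terminal)
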