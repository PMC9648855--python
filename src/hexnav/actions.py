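"""Action spaces (allocentric / egocentric / full) and transition dynamics.

Allocentric actions are referenced to world-fixed lattice directions: move
one step in direction d, or rotate in place to absolute heading h.  Egocentric
actions are referenced to the agent's body: step forward along the current
heading, or turn in place by 60 degrees left/right.  The full space combines
the 12 allocentric actions with four copies of each of the 3 egocentric ones
(24 actions total) so neither reference frame is favoured by sheer count;
copies are distinct output units with identical physical effect.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

from .arena import GridGraph, Pose, rotate_heading, N_HEADINGS

ALLO_MOVE = "allo_move"
ALLO_ROTATE = "allo_rotate"
EGO_FORWARD = "ego_forward"
EGO_TURN_LEFT = "ego_turn_left"
EGO_TURN_RIGHT = "ego_turn_right"

_ALLO_FAMILIES = (ALLO_MOVE, ALLO_ROTATE)
_EGO_FAMILIES = (EGO_FORWARD, EGO_TURN_LEFT, EGO_TURN_RIGHT)


@dataclass(frozen=True)
class Action:
    family: str
    parameter: int | None = None   # direction/heading 0..5 for allo families
    copy_index: int = 0

    def __post_init__(self):
        if self.family in _ALLO_FAMILIES:
            if self.parameter is None or not 0 <= self.parameter < N_HEADINGS:
                raise ValueError("allocentric action needs parameter 0..5")
        elif self.family in _EGO_FAMILIES:
            if self.parameter is not None:
                raise ValueError("egocentric action carries no parameter")
        else:
            raise ValueError(f"unknown action family {self.family!r}")

    @property
    def is_allocentric(self) -> bool:
        return self.family in _ALLO_FAMILIES


@dataclass(frozen=True)
class StepOutcome:
    new_pose: Pose
    collided: bool


class ActionSpace:
    """Ordered, stable list of actions; order fixes output-unit indices."""

    def __init__(self, name: str, actions: list[Action]):
        self.name = name
        self.actions = list(actions)

    def __len__(self) -> int:
        return len(self.actions)

    def __getitem__(self, i: int) -> Action:
        return self.actions[i]

    def allocentric_mask(self):
        """Boolean list: True where the action belongs to the allocentric block."""
        return [a.is_allocentric for a in self.actions]

    def to_csv(self, path=None) -> str:
        buf = io.StringIO()
        buf.write("index,family,parameter,copy_index\n")
        for i, a in enumerate(self.actions):
            p = "" if a.parameter is None else a.parameter
            buf.write(f"{i},{a.family},{p},{a.copy_index}\n")
        text = buf.getvalue()
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def build_action_space(name: str, copies: int = 4) -> ActionSpace:
    """Construct one of the three action spaces.

    Ordering: allocentric block first (6 moves by direction, then 6 absolute
    rotations by target heading), then the egocentric block (forward, left,
    right) repeated once per copy.  ``copies`` applies only to the full
    space's egocentric block.
    """
    if copies < 1:
        raise ValueError("copies must be >= 1")
    allo = [Action(ALLO_MOVE, d) for d in range(N_HEADINGS)]
    allo += [Action(ALLO_ROTATE, h) for h in range(N_HEADINGS)]
    ego = [Action(f) for f in _EGO_FAMILIES]
    if name == "allocentric":
        return ActionSpace(name, allo)
    if name == "egocentric":
        return ActionSpace(name, ego)
    if name == "full":
        dup = [Action(f, copy_index=c) for c in range(copies) for f in _EGO_FAMILIES]
        return ActionSpace(name, allo + dup)
    raise ValueError(f"unknown action space {name!r}")


def apply_action(pose: Pose, action: Action, grid: GridGraph) -> StepOutcome:
    """Deterministic transition: rotations/turns change heading only and never
    collide; moves attempt the lattice step and, when the target neighbor is
    absent (wall or corner), the agent simply remains in place with
    ``collided=True``.
    """
    if action.family == ALLO_ROTATE:
        return StepOutcome(Pose(pose.node, action.parameter), False)
    if action.family == EGO_TURN_LEFT:
        return StepOutcome(Pose(pose.node, rotate_heading(pose.heading, +1)), False)
    if action.family == EGO_TURN_RIGHT:
        return StepOutcome(Pose(pose.node, rotate_heading(pose.heading, -1)), False)
    if action.family == ALLO_MOVE:
        direction = action.parameter
    else:  # EGO_FORWARD: move along the current heading
        direction = pose.heading
    target = grid.neighbor(pose.node, direction)
    if target < 0:
        return StepOutcome(Pose(pose.node, pose.heading), True)
    return StepOutcome(Pose(target, pose.heading), False)
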