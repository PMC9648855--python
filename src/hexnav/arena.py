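"""Hexagonal movement lattice inside a square arena, and pose/heading arithmetic.

The agent moves on a hexagonal grid of nodes spaced ``node_spacing`` metres
apart, clipped to the interior of a square arena of side ``side_length``.
One lattice axis is aligned with the arena's x-axis and the lattice is
anchored at the arena centre (a node sits at the centre).  Headings are
discrete: heading ``k`` (0..5) points at azimuth ``60*k`` degrees measured
counter-clockwise from the +x axis, matching the six lattice directions.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

N_HEADINGS = 6
SECTOR_DEG = 60.0

#: axial-coordinate step for each of the six lattice directions, using the
#: hex basis u=(1,0), v=(1/2, sqrt(3)/2) so every step has unit length.
_AXIAL_STEPS = ((1, 0), (0, 1), (-1, 1), (-1, 0), (0, -1), (1, -1))

# default wall colours (south, east, north, west); pure red is reserved
# for the goal cue cylinder so walls stay visually distinct from it
DEFAULT_WALL_COLORS = (
    (0.15, 0.35, 0.95),   # blue
    (0.15, 0.85, 0.25),   # green
    (0.95, 0.85, 0.10),   # yellow
    (0.85, 0.15, 0.85),   # magenta
)


def heading_angle(h: int) -> float:
    """Azimuth of heading ``h`` in radians (counter-clockwise from +x)."""
    return math.radians(SECTOR_DEG * (h % N_HEADINGS))


def heading_vector(h: int) -> np.ndarray:
    """Unit vector pointing along heading ``h``."""
    a = heading_angle(h)
    return np.array([math.cos(a), math.sin(a)])


def rotate_heading(h: int, delta: int) -> int:
    """Rotate heading ``h`` by ``delta`` sectors of 60 degrees (signed)."""
    return (h + delta) % N_HEADINGS


@dataclass
class ArenaConfig:
    """Static description of one arena.

    Coordinates are centred: walls sit at ``x = +-side_length/2`` and
    ``y = +-side_length/2``.  ``lighting_mode`` is 'high' or 'medium' for
    point lights, 'low' for a uniform distant light; together with
    ``walls_present`` it encodes the spatial-information manipulations
    (high = walls + point lights, medium = point lights only,
    low = uniform light only).
    """

    side_length: float = 2.75
    node_spacing: float = 0.25
    walls_present: bool = True
    lighting_mode: str = "high"
    wall_colors: tuple = DEFAULT_WALL_COLORS
    goal_node: int | None = None
    cue_node: int | None = None

    def __post_init__(self):
        if self.side_length <= 0:
            raise ValueError("side_length must be positive")
        if self.node_spacing <= 0:
            raise ValueError("node_spacing must be positive")
        if self.lighting_mode not in ("high", "medium", "low"):
            raise ValueError(f"unknown lighting_mode {self.lighting_mode!r}")
        if len(self.wall_colors) != 4:
            raise ValueError("need exactly 4 wall colors")

    # -- plain-text serialization ------------------------------------------
    def to_yaml(self, path=None) -> str:
        d = asdict(self)
        d["wall_colors"] = [list(c) for c in self.wall_colors]
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "ArenaConfig":
        if hasattr(source, "read"):
            d = yaml.safe_load(source)
        else:
            try:
                with open(source) as fh:
                    d = yaml.safe_load(fh)
            except (OSError, ValueError):
                d = yaml.safe_load(source)
        d["wall_colors"] = tuple(tuple(c) for c in d["wall_colors"])
        return cls(**d)


@dataclass
class Pose:
    """Agent state on the lattice: node id plus discrete heading 0..5."""

    node: int
    heading: int

    def __post_init__(self):
        self.heading %= N_HEADINGS


class GridGraph:
    """Hexagonal lattice clipped to the arena square.

    Attributes
    ----------
    positions : (n, 2) float array of node positions in metres.
    neighbors : (n, 6) int array; ``neighbors[i, d]`` is the node reached
        from ``i`` by one step in lattice direction ``d``, or -1 if that
        step would leave the arena.
    spacing : edge length in metres.
    """

    def __init__(self, positions: np.ndarray, neighbors: np.ndarray, spacing: float):
        self.positions = np.asarray(positions, dtype=float)
        self.neighbors = np.asarray(neighbors, dtype=int)
        self.spacing = float(spacing)

    @property
    def n_nodes(self) -> int:
        return len(self.positions)

    def neighbor(self, node: int, direction: int) -> int:
        """Neighbor id in lattice ``direction`` (0..5), or -1 at a wall."""
        return int(self.neighbors[node, direction % N_HEADINGS])

    def degree(self, node: int) -> int:
        return int((self.neighbors[node] >= 0).sum())

    def nearest_node(self, xy) -> int:
        d2 = ((self.positions - np.asarray(xy)) ** 2).sum(axis=1)
        return int(np.argmin(d2))

    def to_csv(self, path=None) -> str:
        buf = io.StringIO()
        buf.write("node,x,y,n0,n1,n2,n3,n4,n5\n")
        for i, (x, y) in enumerate(self.positions):
            nbrs = ",".join(str(n) for n in self.neighbors[i])
            buf.write(f"{i},{x:.6f},{y:.6f},{nbrs}\n")
        text = buf.getvalue()
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def build_grid(config: ArenaConfig) -> GridGraph:
    """Build the maximal hexagonal lattice whose nodes lie strictly inside
    the arena square, with 6-way adjacency indexed by lattice direction.

    Raises
    ------
    ValueError
        If ``node_spacing >= side_length`` (degenerate grid).
    """
    s = config.node_spacing
    half = config.side_length / 2.0
    if s >= config.side_length:
        raise ValueError("degenerate grid: node_spacing >= side_length")

    rmax = int(math.ceil(config.side_length / s)) + 1
    coords = {}
    positions = []
    for r in range(-rmax, rmax + 1):
        y = s * r * math.sqrt(3) / 2.0
        if abs(y) >= half:
            continue
        for q in range(-2 * rmax, 2 * rmax + 1):
            x = s * (q + r / 2.0)
            if abs(x) >= half:
                continue
            coords[(q, r)] = len(positions)
            positions.append((x, y))

    n = len(positions)
    neighbors = np.full((n, N_HEADINGS), -1, dtype=int)
    for (q, r), i in coords.items():
        for d, (dq, dr) in enumerate(_AXIAL_STEPS):
            j = coords.get((q + dq, r + dr))
            if j is not None:
                neighbors[i, d] = j
    return GridGraph(np.array(positions), neighbors, s)
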