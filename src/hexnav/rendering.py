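"""Procedural panoramic vision: 48x12 RGB observations with a 240-degree FOV.

The agent's visual input is a low-resolution panorama rendered by casting one
ray per image column from the agent's position.  Column ``c`` (0..47) looks
along azimuth ``heading*60 - 120 + 240*(c+0.5)/48`` degrees, so the field of
view is centred on the current heading and a 60-degree rotation shifts the
panorama by exactly 12 columns (columns imaging the same world azimuth are
bit-identical across headings).

Geometry is deliberately minimal but information-preserving:

* the four arena walls carry four distinct colours (distal landmarks);
  the nearest wall hit by a column's ray sets that column's surface colour,
* apparent distance is encoded vertically: a surface at distance ``d`` fills
  a band of half-height ``(H/2)/(1 + d/d0)`` rows around the horizon
  (``d0 = side_length/4``), so nearer surfaces look taller,
* the goal cue is a red cylinder (radius 0.10 m) drawn in front of walls,
* two point lights above opposite corners brighten columns whose azimuth
  points near a light, with 1/distance falloff — a second, colour-free
  source of spatial information,
* the 'low' lighting mode removes walls' and lights' azimuthal structure:
  a fixed sky/floor gradient under uniform light, plus the cue if present.

Everything is a deterministic function of (position, heading, arena, cue),
which the activity-map analysis relies on.
"""

from __future__ import annotations

import numpy as np

from .arena import ArenaConfig, GridGraph, Pose

IMG_H = 12
IMG_W = 48
FOV_DEG = 240.0
CUE_RADIUS = 0.10          # metres
CUE_COLOR = np.array([1.0, 0.0, 0.0])
SKY_COLOR = np.array([0.55, 0.70, 0.90])
FLOOR_COLOR = np.array([0.25, 0.22, 0.20])
_AMBIENT = 0.55            # base brightness under point lights
_LIGHT_GAIN = 0.45
_LIGHT_SIGMA_DEG = 25.0    # angular width of a light's glow
_UNIFORM_BRIGHTNESS = 0.85  # 'low' mode distant-light level
_HORIZON = IMG_H // 2


def column_azimuths(heading: int) -> np.ndarray:
    """World azimuth (radians) of each image column under ``heading``."""
    c = np.arange(IMG_W)
    az_deg = 60.0 * heading + (FOV_DEG / IMG_W) * c + (FOV_DEG / IMG_W) * 0.5 - 120.0
    # canonicalize in degrees (exact for these half-degree values) so columns
    # imaging the same world azimuth are bit-identical across headings
    return np.deg2rad(az_deg % 360.0)


def _wall_hits(pos, dirs, half):
    """Nearest wall per ray: returns (distance, wall index 0..3).

    Wall indices: 0 south (y=-half), 1 east (x=+half), 2 north (y=+half),
    3 west (x=-half).
    """
    x, y = pos
    dx, dy = dirs[:, 0], dirs[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.full((4, len(dirs)), np.inf)
        t[0] = np.where(dy < 0, (-half - y) / dy, np.inf)
        t[1] = np.where(dx > 0, (half - x) / dx, np.inf)
        t[2] = np.where(dy > 0, (half - y) / dy, np.inf)
        t[3] = np.where(dx < 0, (-half - x) / dx, np.inf)
    wall = np.argmin(t, axis=0)
    dist = t[wall, np.arange(len(dirs))]
    return dist, wall


def _cue_hits(pos, dirs, cue_xy):
    """Ray/cylinder intersection distance per ray (inf where missed)."""
    rel = np.asarray(cue_xy, dtype=float) - np.asarray(pos, dtype=float)
    b = dirs @ rel                      # projection of cue centre on each ray
    c = rel @ rel - CUE_RADIUS ** 2
    disc = b * b - c
    hit = (disc >= 0) & (b > 0)
    dist = np.full(len(dirs), np.inf)
    if np.any(hit):
        t = b[hit] - np.sqrt(disc[hit])
        t = np.maximum(t, 0.0)          # agent standing inside the cylinder
        dist[hit] = t
    return dist


def _band_rows(dist, d0):
    """Vertical extent (top, bottom row) of a surface at distance ``dist``."""
    h = (IMG_H / 2.0) / (1.0 + dist / d0)
    top = np.rint(_HORIZON - h).astype(int).clip(0, IMG_H - 1)
    bot = np.rint(_HORIZON + h).astype(int).clip(top + 1, IMG_H)
    return top, bot


def _brightness(pos, az, arena: ArenaConfig) -> np.ndarray:
    """Per-column brightness multiplier from the two corner point lights."""
    if arena.lighting_mode == "low":
        return np.full(IMG_W, _UNIFORM_BRIGHTNESS)
    half = arena.side_length / 2.0
    b = np.full(IMG_W, _AMBIENT)
    sigma = np.deg2rad(_LIGHT_SIGMA_DEG)
    for corner in ((-half, -half), (half, half)):
        rel = np.asarray(corner) - np.asarray(pos, dtype=float)
        d = max(np.hypot(*rel), 0.3)
        laz = np.arctan2(rel[1], rel[0])
        dphi = np.angle(np.exp(1j * (az - laz)))    # wrapped difference
        b = b + _LIGHT_GAIN * np.exp(-0.5 * (dphi / sigma) ** 2) / d
    return np.clip(b, 0.0, 1.0)


def render(position, heading: int, arena: ArenaConfig, cue_xy=None) -> np.ndarray:
    """Render the (12, 48, 3) observation at a continuous ``position``.

    ``cue_xy`` places the red cue cylinder; ``None`` renders no cue (guidance:
    the goal is unmarked).  Output intensities lie in [0, 1].
    """
    pos = np.asarray(position, dtype=float)
    az = column_azimuths(heading)
    dirs = np.stack([np.cos(az), np.sin(az)], axis=1)
    half = arena.side_length / 2.0
    d0 = arena.side_length / 4.0
    bright = _brightness(pos, az, arena)

    img = np.empty((IMG_H, IMG_W, 3))
    # fixed sky/floor gradient (row-dependent only): brighter sky near the
    # horizon, darker floor further down — constant across columns
    row_shade = np.concatenate([
        np.linspace(0.8, 1.0, _HORIZON),          # sky rows, top to horizon
        np.linspace(1.0, 0.7, IMG_H - _HORIZON),  # floor rows, horizon down
    ])
    img[:_HORIZON] = SKY_COLOR
    img[_HORIZON:] = FLOOR_COLOR
    img *= row_shade[:, None, None]
    img *= bright[None, :, None]

    surf_color = None
    if arena.walls_present:
        wdist, wall = _wall_hits(pos, dirs, half)
        surf_dist = wdist
        surf_color = np.asarray(arena.wall_colors, dtype=float)[wall]
    else:
        surf_dist = np.full(IMG_W, np.inf)

    if cue_xy is not None:
        cdist = _cue_hits(pos, dirs, cue_xy)
        cue_mask = cdist < surf_dist
        if surf_color is None:
            surf_color = np.zeros((IMG_W, 3))
        surf_dist = np.where(cue_mask, cdist, surf_dist)
        surf_color = np.where(cue_mask[:, None], CUE_COLOR[None, :], surf_color)

    if surf_color is not None:
        finite = np.isfinite(surf_dist)
        top, bot = _band_rows(np.where(finite, surf_dist, 1e9), d0)
        for c in np.flatnonzero(finite):
            img[top[c]:bot[c], c] = surf_color[c] * bright[c]

    return np.clip(img, 0.0, 1.0)


def observe(pose: Pose, arena: ArenaConfig, grid: GridGraph,
            cue_node: int | None = None) -> np.ndarray:
    """Observation at a lattice pose; the cue defaults to ``arena.cue_node``."""
    cue = cue_node if cue_node is not None else arena.cue_node
    cue_xy = grid.positions[cue] if cue is not None else None
    return render(grid.positions[pose.node], pose.heading, arena, cue_xy)


def contact_sheet(arena: ArenaConfig, grid: GridGraph, position=None, path=None):
    """Render the six headings at one position into a matplotlib figure
    (debugging fixture; saved as PNG when ``path`` is given)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if position is None:
        position = (0.0, 0.0)
    cue_xy = grid.positions[arena.cue_node] if arena.cue_node is not None else None
    fig, axes = plt.subplots(6, 1, figsize=(6, 7))
    for h, ax in enumerate(axes):
        ax.imshow(render(position, h, arena, cue_xy))
        ax.set_ylabel(f"h={h}")
        ax.set_xticks([]), ax.set_yticks([])
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return fig
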