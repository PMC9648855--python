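"""Spatial activity maps of the 50 analysis-layer units, their classification
into place / egocentric-vector / head-direction-modulated / view-selective /
other cells, coverage entropy, and synthetic fixture maps with known labels.

Activity maps sample the unit activations on a 25 x 25 grid of bin centres
spanning the square arena, for each of the six headings, then smooth each
heading slice with a Gaussian filter (sigma = 2 bins, edge-replicating
boundaries).  *Position maps* move the agent (guidance analysis); *cue maps*
fix the agent at the arena centre and move the goal cue (aiming analysis).

Classification cascade (mutually exclusive, first match wins):

1. near-silent unit (peak below 1% of the layer-wide maximum) -> other
2. active in at most ``n_view`` of the 6 headings (a heading is active when
   its peak reaches ``theta_view`` of the unit's global peak) -> view_selective
3. localized fields (area of the >=15%-of-peak mask under 50% of the arena)
   whose centres agree across headings within 5% of arena size -> place
4. localized fields whose centres sit at one fixed *egocentric* distance and
   direction (allocentric offsets from the reference point, rotated into the
   body frame by -60 deg * heading, agree within 5% of arena size in length
   and one 60-degree sector in angle) -> ego_vector
5. localized fields otherwise -> hd_modulated
6. everything else -> other

For cue maps the reference point is the agent (arena centre) and the field
sits *at* the cue: ego vector = R(-60h) (centre_h - ref).  For position maps
the field marks where the *agent* is when the referent (the goal) lies at a
fixed egocentric vector, so the relation inverts: ego vector =
R(-60h) (ref - centre_h).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage

from .arena import ArenaConfig, GridGraph, SECTOR_DEG
from .rendering import render

MAP_BINS = 25
N_HEADINGS = 6

PLACE = "place"
EGO_VECTOR = "ego_vector"
HD_MODULATED = "hd_modulated"
VIEW_SELECTIVE = "view_selective"
OTHER = "other"
CLASS_LABELS = (PLACE, EGO_VECTOR, HD_MODULATED, VIEW_SELECTIVE, OTHER)


# ---------------------------------------------------------------------------
# Map computation
# ---------------------------------------------------------------------------

def bin_centers(side_length: float) -> np.ndarray:
    """Centres of the 25 bins along one axis of the (centred) arena square."""
    cell = side_length / MAP_BINS
    return -side_length / 2 + cell * (np.arange(MAP_BINS) + 0.5)


def bin_to_xy(ij, side_length: float) -> np.ndarray:
    """Bin coordinates (possibly fractional) to arena xy, elementwise."""
    cell = side_length / MAP_BINS
    return -side_length / 2 + cell * (np.asarray(ij, dtype=float) + 0.5)


def xy_to_bin(xy, side_length: float) -> np.ndarray:
    cell = side_length / MAP_BINS
    return (np.asarray(xy, dtype=float) + side_length / 2) / cell - 0.5


@dataclass
class ActivityMaps:
    """Per-unit activation over the 25x25 grid and 6 headings.

    ``values[u, ix, iy, h]`` is unit ``u``'s (smoothed) activation with the
    sampled point at x-bin ``ix``, y-bin ``iy``, heading ``h``.
    """

    values: np.ndarray                  # (n_units, 25, 25, 6), nonnegative
    mode: str                           # 'position_maps' | 'cue_maps'
    arena: ArenaConfig
    smoothing_sigma: float = 2.0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 4 or v.shape[1:] != (MAP_BINS, MAP_BINS, N_HEADINGS):
            raise ValueError("activity maps must have shape (units, 25, 25, 6)")
        self.values = v

    @property
    def n_units(self) -> int:
        return len(self.values)

    def unit(self, u: int) -> np.ndarray:
        return self.values[u]

    def direction_averaged(self) -> np.ndarray:
        return self.values.mean(axis=3)


def smooth_map_stack(raw: np.ndarray, sigma: float = 2.0) -> np.ndarray:
    """Gaussian-smooth each heading slice independently (sigma in bins,
    edge replication at the borders).  Linear, so slice order is irrelevant."""
    if sigma <= 0:
        return raw.copy()
    return ndimage.gaussian_filter(
        raw, sigma=sigma, axes=(-3, -2), mode="nearest")


def _feature_batch(network, obs_list, chunk: int = 256) -> np.ndarray:
    obs = np.stack(obs_list)
    outs = [network.features(obs[i:i + chunk]) for i in range(0, len(obs), chunk)]
    return np.concatenate(outs, axis=0)


def compute_position_maps(network, arena: ArenaConfig, grid: GridGraph,
                          cue_node: int | None = None,
                          smoothing_sigma: float = 2.0) -> ActivityMaps:
    """Record analysis-layer activations with the agent at each of the 25x25
    continuous positions (not snapped to lattice nodes) for all 6 headings,
    then smooth.  Evaluation mode: dropout off, no noise."""
    centers = bin_centers(arena.side_length)
    cue_xy = grid.positions[cue_node] if cue_node is not None else None
    n_units = network.features(render((0.0, 0.0), 0, arena, cue_xy)).shape[-1]
    raw = np.empty((n_units, MAP_BINS, MAP_BINS, N_HEADINGS))
    for h in range(N_HEADINGS):
        obs = [render((x, y), h, arena, cue_xy)
               for x in centers for y in centers]
        feats = _feature_batch(network, obs)      # (625, n_units)
        raw[:, :, :, h] = feats.T.reshape(n_units, MAP_BINS, MAP_BINS)
    return ActivityMaps(smooth_map_stack(raw, smoothing_sigma),
                        "position_maps", arena, smoothing_sigma)


def compute_cue_maps(network, arena: ArenaConfig,
                     smoothing_sigma: float = 2.0) -> ActivityMaps:
    """Agent fixed at the arena centre; the cue visits each of the 25x25
    positions, for each of the 6 headings."""
    centers = bin_centers(arena.side_length)
    n_units = network.features(render((0.0, 0.0), 0, arena, (0.1, 0.1))).shape[-1]
    raw = np.empty((n_units, MAP_BINS, MAP_BINS, N_HEADINGS))
    for h in range(N_HEADINGS):
        obs = [render((0.0, 0.0), h, arena, (x, y))
               for x in centers for y in centers]
        feats = _feature_batch(network, obs)
        raw[:, :, :, h] = feats.T.reshape(n_units, MAP_BINS, MAP_BINS)
    return ActivityMaps(smooth_map_stack(raw, smoothing_sigma),
                        "cue_maps", arena, smoothing_sigma)


# ---------------------------------------------------------------------------
# Field extraction and classification
# ---------------------------------------------------------------------------

@dataclass
class FieldDescriptor:
    peak_value: float
    mask: np.ndarray            # >=15%-of-peak mask over the full map
    component_mask: np.ndarray  # connected component containing the peak
    area_fraction: float        # |mask| / 625
    centroid: np.ndarray        # activation-weighted centre of the component, bins
    localized: bool             # area_fraction < 0.5


def extract_field(map_2d: np.ndarray, peak_fraction: float = 0.15,
                  localized_below: float = 0.5) -> FieldDescriptor | None:
    """Field of one heading slice: threshold at 15% of the peak, keep the
    connected component containing the peak, return its activation-weighted
    centroid.  ``None`` for an all-zero map."""
    m = np.asarray(map_2d, dtype=float)
    peak = float(m.max())
    if peak <= 0:
        return None
    mask = m >= peak_fraction * peak
    labels, _ = ndimage.label(mask)
    peak_idx = np.unravel_index(np.argmax(m), m.shape)
    comp = labels == labels[peak_idx]
    w = m * comp
    total = w.sum()
    ix, iy = np.meshgrid(np.arange(m.shape[0]), np.arange(m.shape[1]), indexing="ij")
    centroid = np.array([(w * ix).sum() / total, (w * iy).sum() / total])
    area_fraction = mask.sum() / m.size
    return FieldDescriptor(peak, mask, comp, float(area_fraction), centroid,
                           bool(area_fraction < localized_below))


@dataclass
class ClassifierParams:
    """Thresholds of the decision cascade (fractions of arena size are
    expressed in bins: 5% of the arena is 1.25 of the 25 bins)."""

    theta_view: float = 0.2        # heading active if peak >= 20% of global peak
    n_view: int = 2                # view_selective: active in <= 2 headings
    place_tol_bins: float = 0.05 * MAP_BINS
    ego_dist_tol_bins: float = 0.05 * MAP_BINS
    ego_angle_tol_deg: float = SECTOR_DEG
    activity_floor: float = 0.01   # of the layer-wide maximum
    peak_fraction: float = 0.15
    localized_below: float = 0.5


@dataclass
class UnitClass:
    label: str
    evidence: dict = dc_field(default_factory=dict)


def _rot(v, deg):
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def _circular_spread_deg(angles_deg):
    """Smallest arc (degrees) containing all angles."""
    a = np.sort(np.mod(angles_deg, 360.0))
    if len(a) < 2:
        return 0.0
    gaps = np.diff(np.concatenate([a, [a[0] + 360.0]]))
    return 360.0 - gaps.max()


def classify_unit(maps: np.ndarray, mode: str, arena: ArenaConfig,
                  reference_xy=None, layer_max: float | None = None,
                  params: ClassifierParams | None = None) -> UnitClass:
    """Label one unit from its (25, 25, 6) heading maps.

    ``reference_xy`` is the referent for the egocentric-vector test: the
    agent position for cue maps (defaults to the arena centre) and the goal
    position for position maps (defaults to the centre when no goal is set).
    """
    p = params or ClassifierParams()
    maps = np.asarray(maps, dtype=float)
    global_peak = float(maps.max())

    floor = p.activity_floor * layer_max if layer_max is not None else 0.0
    if global_peak <= max(floor, 0.0):
        return UnitClass(OTHER, {"reason": "near_silent", "global_peak": global_peak})

    head_peaks = maps.max(axis=(0, 1))
    active = head_peaks >= p.theta_view * global_peak
    evidence = {"head_peaks": head_peaks, "active": active}
    if active.sum() <= p.n_view:
        evidence["reason"] = "few_active_headings"
        return UnitClass(VIEW_SELECTIVE, evidence)

    fields = {h: extract_field(maps[:, :, h], p.peak_fraction, p.localized_below)
              for h in np.flatnonzero(active)}
    if any(f is None for f in fields.values()):
        evidence["reason"] = "active_heading_without_field"
        return UnitClass(OTHER, evidence)
    all_localized = all(f.localized for f in fields.values())
    centroids = {h: f.centroid for h, f in fields.items()}
    evidence["centroids"] = centroids
    evidence["area_fractions"] = {h: f.area_fraction for h, f in fields.items()}

    if all_localized:
        pts = np.array(list(centroids.values()))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        evidence["max_center_shift_bins"] = float(d.max())
        if d.max() <= p.place_tol_bins:
            evidence["reason"] = "stable_localized_field"
            return UnitClass(PLACE, evidence)

        # egocentric-vector test in bin coordinates
        if reference_xy is None:
            ref = np.array([(MAP_BINS - 1) / 2.0, (MAP_BINS - 1) / 2.0])
        else:
            ref = xy_to_bin(reference_xy, arena.side_length)
        ego = {}
        for h, c in centroids.items():
            v = (c - ref) if mode == "cue_maps" else (ref - c)
            ego[h] = _rot(v, -SECTOR_DEG * h)
        dists = np.array([np.linalg.norm(v) for v in ego.values()])
        angs = np.array([np.degrees(np.arctan2(v[1], v[0])) for v in ego.values()])
        evidence["ego_vectors"] = ego
        evidence["ego_dist_spread_bins"] = float(dists.max() - dists.min())
        evidence["ego_angle_spread_deg"] = _circular_spread_deg(angs)
        if (dists.max() - dists.min() <= p.ego_dist_tol_bins
                and evidence["ego_angle_spread_deg"] <= p.ego_angle_tol_deg):
            evidence["reason"] = "consistent_egocentric_vector"
            evidence["ego_distance_bins"] = float(dists.mean())
            return UnitClass(EGO_VECTOR, evidence)

        evidence["reason"] = "localized_heading_dependent_field"
        return UnitClass(HD_MODULATED, evidence)

    evidence["reason"] = "no_localized_fields"
    return UnitClass(OTHER, evidence)


def classify_population(amaps: ActivityMaps, reference_xy=None,
                        params: ClassifierParams | None = None):
    """Classify every unit; returns (table, counts, proportions) with the
    counts summing to the number of units."""
    layer_max = float(amaps.values.max())
    rows = []
    for u in range(amaps.n_units):
        uc = classify_unit(amaps.unit(u), amaps.mode, amaps.arena,
                           reference_xy=reference_xy, layer_max=layer_max,
                           params=params)
        ev = uc.evidence
        rows.append({
            "unit": u,
            "label": uc.label,
            "reason": ev.get("reason", ""),
            "n_active_headings": int(ev["active"].sum()) if "active" in ev else 0,
            "max_center_shift_bins": ev.get("max_center_shift_bins", np.nan),
            "ego_distance_bins": ev.get("ego_distance_bins", np.nan),
        })
    table = pd.DataFrame(rows)
    counts = {lbl: int((table["label"] == lbl).sum()) for lbl in CLASS_LABELS}
    total = amaps.n_units
    proportions = {lbl: c / total for lbl, c in counts.items()}
    return table, counts, proportions


# ---------------------------------------------------------------------------
# Coverage entropy
# ---------------------------------------------------------------------------

def shannon_entropy_bits(p: np.ndarray) -> float:
    """H = -sum p log2 p with 0 log 0 = 0; p need not be pre-normalized."""
    p = np.asarray(p, dtype=float).ravel()
    total = p.sum()
    if total <= 0:
        raise ValueError("entropy of an empty distribution")
    p = p / total
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


@dataclass
class CoverageStats:
    probabilities: np.ndarray        # (25, 25), sums to 1
    entropy_bits: float
    field_centers: np.ndarray        # (k, 2) bin coordinates
    mean_center_to_goal_bins: float | None


def coverage_entropy(place_maps: np.ndarray, goal_xy=None,
                     side_length: float | None = None) -> CoverageStats:
    """Coverage of the arena by the place-cell population: sum the
    direction-averaged maps over units, normalize to a distribution, and take
    the Shannon entropy (log2 625 = 9.288 bits for uniform coverage).

    ``place_maps`` is (n_units, 25, 25, 6) or already direction-averaged
    (n_units, 25, 25).  Raises ``ValueError("empty class")`` without units.
    """
    m = np.asarray(place_maps, dtype=float)
    if m.ndim == 4:
        m = m.mean(axis=3)
    if m.ndim != 3 or len(m) == 0:
        raise ValueError("empty class")
    summed = m.sum(axis=0)
    if summed.sum() <= 0:
        raise ValueError("empty class")
    prob = summed / summed.sum()
    centers = []
    for unit_map in m:
        f = extract_field(unit_map)
        if f is not None:
            centers.append(f.centroid)
    centers = np.array(centers) if centers else np.empty((0, 2))
    mean_dist = None
    if goal_xy is not None and len(centers) and side_length is not None:
        gb = xy_to_bin(goal_xy, side_length)
        mean_dist = float(np.linalg.norm(centers - gb, axis=1).mean())
    return CoverageStats(prob, shannon_entropy_bits(prob), centers, mean_dist)


# ---------------------------------------------------------------------------
# Synthetic fixture maps (known ground truth for the classifier)
# ---------------------------------------------------------------------------

def _bump(center, sigma, amplitude=1.0):
    ix, iy = np.meshgrid(np.arange(MAP_BINS), np.arange(MAP_BINS), indexing="ij")
    return amplitude * np.exp(-((ix - center[0]) ** 2 + (iy - center[1]) ** 2)
                              / (2.0 * sigma ** 2))


def generate_fixture_maps(label: str, rng: np.random.Generator,
                          mode: str = "cue_maps", bump_sigma: float = 1.75,
                          amplitude: float = 1.0, noise: float = 0.0,
                          radius_bins: float | None = None,
                          angle_deg: float | None = None,
                          center=None, active_headings=None):
    """Synthetic (25, 25, 6) heading maps realizing one class's defining
    geometry, with the ground-truth parameters attached.

    ``noise`` adds uniform positive noise of that fraction of the bump
    amplitude to every bin (keeps maps nonnegative, as rectifier outputs are).
    """
    ref = np.array([(MAP_BINS - 1) / 2.0, (MAP_BINS - 1) / 2.0])
    maps = np.zeros((MAP_BINS, MAP_BINS, N_HEADINGS))
    truth = {"label": label, "mode": mode}

    if label == PLACE:
        c = np.asarray(center) if center is not None \
            else rng.uniform(5, MAP_BINS - 6, size=2)
        truth["center"] = c
        for h in range(N_HEADINGS):
            maps[:, :, h] = _bump(c, bump_sigma, amplitude)
    elif label == EGO_VECTOR:
        r = radius_bins if radius_bins is not None else rng.uniform(3.5, 7.0)
        beta = angle_deg if angle_deg is not None else rng.uniform(0, 360)
        v = r * np.array([np.cos(np.deg2rad(beta)), np.sin(np.deg2rad(beta))])
        truth.update(radius_bins=r, angle_deg=beta)
        sign = 1.0 if mode == "cue_maps" else -1.0
        for h in range(N_HEADINGS):
            c_h = ref + sign * _rot(v, SECTOR_DEG * h)
            maps[:, :, h] = _bump(c_h, bump_sigma, amplitude)
    elif label == HD_MODULATED:
        # localized per-heading fields that are neither position-stable nor
        # consistent with a single egocentric vector: alternate two radii and
        # jitter the angles away from the body-frame relation
        r1, r2 = 3.0, 7.5
        base = rng.uniform(0, 360)
        centers = []
        for h in range(N_HEADINGS):
            r = r1 if h % 2 == 0 else r2
            ang = base + 360.0 / N_HEADINGS * h * rng.choice([0.3, 1.9])
            c_h = ref + r * np.array([np.cos(np.deg2rad(ang)), np.sin(np.deg2rad(ang))])
            centers.append(c_h)
            maps[:, :, h] = _bump(c_h, bump_sigma, amplitude)
        truth["centers"] = np.array(centers)
    elif label == VIEW_SELECTIVE:
        k = rng.integers(1, 3)  # active in 1 or 2 headings
        hs = active_headings if active_headings is not None \
            else rng.choice(N_HEADINGS, size=k, replace=False)
        c = np.asarray(center) if center is not None \
            else rng.uniform(5, MAP_BINS - 6, size=2)
        truth.update(active_headings=np.atleast_1d(hs), center=c)
        for h in np.atleast_1d(hs):
            maps[:, :, h] = _bump(c, bump_sigma, amplitude)
    elif label == OTHER:
        # broad, non-localized activity in every heading
        maps[:] = 0.6 * amplitude + 0.05 * amplitude * rng.random(maps.shape)
    else:
        raise ValueError(f"unknown class label {label!r}")

    if noise > 0:
        maps = maps + rng.uniform(0, noise * amplitude, size=maps.shape)
    return maps, truth


# ---------------------------------------------------------------------------
# Storage and figures
# ---------------------------------------------------------------------------

def save_maps(amaps: ActivityMaps, path):
    """Hierarchical container: one group per unit, one dataset per heading."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["mode"] = amaps.mode
        f.attrs["smoothing_sigma"] = amaps.smoothing_sigma
        f.attrs["arena_yaml"] = amaps.arena.to_yaml()
        for u in range(amaps.n_units):
            grp = f.create_group(f"unit_{u:03d}")
            for h in range(N_HEADINGS):
                grp.create_dataset(f"heading_{h}", data=amaps.values[u, :, :, h])


def load_maps(path) -> ActivityMaps:
    import h5py

    with h5py.File(path, "r") as f:
        units = sorted(k for k in f.keys() if k.startswith("unit_"))
        values = np.stack([
            np.stack([f[u][f"heading_{h}"][()] for h in range(N_HEADINGS)], axis=-1)
            for u in units])
        return ActivityMaps(values, str(f.attrs["mode"]),
                            ArenaConfig.from_yaml(str(f.attrs["arena_yaml"])),
                            float(f.attrs["smoothing_sigma"]))


def plot_unit(amaps: ActivityMaps, unit: int, path=None):
    """Contact sheet for one unit: direction-averaged map plus the six
    per-heading maps."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(8, 4))
    gs = fig.add_gridspec(2, 5)
    ax = fig.add_subplot(gs[:, :2])
    ax.imshow(amaps.unit(unit).mean(axis=2).T, origin="lower", cmap="viridis")
    ax.set_title(f"unit {unit} (avg)")
    for h in range(N_HEADINGS):
        axh = fig.add_subplot(gs[h // 3, 2 + h % 3])
        axh.imshow(amaps.unit(unit)[:, :, h].T, origin="lower", cmap="viridis")
        axh.set_title(f"h={h}", fontsize=8)
        axh.set_xticks([]), axh.set_yticks([])
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return fig
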