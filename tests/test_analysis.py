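"""Activity maps, field extraction, unit classification, coverage entropy."""

import numpy as np
import pytest
from scipy import signal

import hexnav as hx
from hexnav.analysis import (MAP_BINS, _rot, bin_to_xy, xy_to_bin,
                             generate_fixture_maps)


# -- smoothing -------------------------------------------------------------

def direct_gaussian_convolution(img, sigma=2.0, truncate=4.0):
    """Independent oracle: explicit sampled-Gaussian kernel, separable
    convolution with edge-replicated borders."""
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    k /= k.sum()
    padded = np.pad(img, radius, mode="edge")
    out = signal.convolve2d(padded, np.outer(k, k), mode="valid")
    return out


def test_smoothing_impulse_matches_convolution_oracle():
    rng = np.random.default_rng(0)
    impulse = np.zeros((MAP_BINS, MAP_BINS))
    impulse[13, 7] = 1.0
    stack = np.zeros((1, MAP_BINS, MAP_BINS, 6))
    stack[0, :, :, 2] = impulse
    sm = hx.smooth_map_stack(stack, sigma=2.0)
    oracle = direct_gaussian_convolution(impulse)
    assert np.abs(sm[0, :, :, 2] - oracle).max() < 1e-10
    # untouched heading slices stay zero
    assert np.all(sm[0, :, :, 0] == 0)
    # also for an arbitrary map, not just an impulse
    arb = rng.random((MAP_BINS, MAP_BINS))
    stack[0, :, :, 5] = arb
    sm = hx.smooth_map_stack(stack, sigma=2.0)
    assert np.abs(sm[0, :, :, 5] - direct_gaussian_convolution(arb)).max() < 1e-10


def test_smoothing_linear_and_slicewise():
    rng = np.random.default_rng(1)
    a = rng.random((2, MAP_BINS, MAP_BINS, 6))
    b = rng.random((2, MAP_BINS, MAP_BINS, 6))
    left = hx.smooth_map_stack(a + 2 * b)
    right = hx.smooth_map_stack(a) + 2 * hx.smooth_map_stack(b)
    assert np.allclose(left, right, atol=1e-12)


# -- field extraction ------------------------------------------------------

def test_extract_field_gaussian_bump_centroid():
    rng = np.random.default_rng(2)
    maps, _ = generate_fixture_maps("place", rng, center=(12, 12), bump_sigma=1.5)
    f = hx.extract_field(maps[:, :, 0])
    assert f is not None and f.localized
    assert np.linalg.norm(f.centroid - np.array([12, 12])) < 0.5


def test_extract_field_edge_cases():
    assert hx.extract_field(np.zeros((25, 25))) is None
    const = hx.extract_field(np.full((25, 25), 3.0))
    assert const.area_fraction == 1.0 and not const.localized


def test_extract_field_keeps_peak_component_only():
    m = np.zeros((25, 25))
    m[5, 5] = 1.0       # main peak
    m[20, 20] = 0.5     # secondary blob above threshold, disconnected
    f = hx.extract_field(m)
    assert f.component_mask[5, 5] and not f.component_mask[20, 20]
    assert np.allclose(f.centroid, [5, 5])


# -- classifier on analytic fixtures ---------------------------------------

@pytest.mark.parametrize("label", hx.CLASS_LABELS)
def test_fixture_classified_correctly_at_zero_noise(label):
    rng = np.random.default_rng(3)
    for _ in range(10):
        maps, truth = generate_fixture_maps(label, rng, noise=0.0)
        got = hx.classify_unit(maps, "cue_maps", hx.ArenaConfig(), layer_max=maps.max())
        assert got.label == label, truth


def test_ego_vector_fixture_recovers_radius():
    rng = np.random.default_rng(4)
    maps, truth = generate_fixture_maps("ego_vector", rng, radius_bins=5.0)
    got = hx.classify_unit(maps, "cue_maps", hx.ArenaConfig(), layer_max=maps.max())
    assert got.label == "ego_vector"
    assert got.evidence["ego_distance_bins"] == pytest.approx(5.0, abs=0.5)


def test_ego_vector_fixture_position_map_relation():
    """The inverse field-to-position relation classifies position-map
    fixtures as ego-vector too."""
    rng = np.random.default_rng(5)
    maps, _ = generate_fixture_maps("ego_vector", rng, mode="position_maps",
                                    radius_bins=6.0)
    got = hx.classify_unit(maps, "position_maps", hx.ArenaConfig(),
                           layer_max=maps.max())
    assert got.label == "ego_vector"


def test_view_selective_single_heading():
    rng = np.random.default_rng(6)
    maps, _ = generate_fixture_maps("view_selective", rng, active_headings=[2],
                                    center=(10, 14))
    got = hx.classify_unit(maps, "cue_maps", hx.ArenaConfig(), layer_max=maps.max())
    assert got.label == "view_selective"
    assert list(np.flatnonzero(got.evidence["active"])) == [2]


def test_near_silent_unit_is_other():
    maps = np.full((25, 25, 6), 1e-6)
    got = hx.classify_unit(maps, "cue_maps", hx.ArenaConfig(), layer_max=100.0)
    assert got.label == "other"
    assert got.evidence["reason"] == "near_silent"


def test_classifier_total_function():
    """Every random nonnegative map gets exactly one of the five labels."""
    rng = np.random.default_rng(7)
    for _ in range(30):
        maps = rng.random((25, 25, 6)) ** rng.integers(1, 6)
        got = hx.classify_unit(maps, "cue_maps", hx.ArenaConfig(),
                               layer_max=maps.max())
        assert got.label in hx.CLASS_LABELS


def test_rotational_equivariance_of_classification():
    """Rotating all fixture geometry by 60 degrees about the reference and
    shifting heading labels by one leaves every classification unchanged."""
    rng = np.random.default_rng(8)
    ref = np.array([12.0, 12.0])
    for label in ("place", "ego_vector", "view_selective"):
        base_kwargs = {}
        if label == "place":
            base_kwargs["center"] = (15.0, 9.0)
        if label == "ego_vector":
            base_kwargs.update(radius_bins=5.0, angle_deg=40.0)
        if label == "view_selective":
            base_kwargs.update(active_headings=[1], center=(15.0, 9.0))
        maps, _ = generate_fixture_maps(label, rng, **base_kwargs)

        rot_kwargs = dict(base_kwargs)
        if "center" in rot_kwargs:
            c = np.asarray(rot_kwargs["center"], dtype=float)
            rot_kwargs["center"] = tuple(ref + _rot(c - ref, 60.0))
        if "angle_deg" in rot_kwargs:
            rot_kwargs["angle_deg"] = rot_kwargs["angle_deg"]  # body-frame: unchanged
        if "active_headings" in rot_kwargs:
            rot_kwargs["active_headings"] = [(h + 1) % 6
                                             for h in rot_kwargs["active_headings"]]
        maps_rot, _ = generate_fixture_maps(label, rng, **rot_kwargs)

        arena = hx.ArenaConfig()
        a = hx.classify_unit(maps, "cue_maps", arena, layer_max=maps.max())
        b = hx.classify_unit(maps_rot, "cue_maps", arena, layer_max=maps_rot.max())
        assert a.label == b.label == label


def test_classify_population_partition():
    rng = np.random.default_rng(9)
    per_class = 10
    values = []
    labels = []
    for label in hx.CLASS_LABELS:
        for _ in range(per_class):
            m, _ = generate_fixture_maps(label, rng, noise=0.0)
            values.append(m)
            labels.append(label)
    amaps = hx.ActivityMaps(np.stack(values), "cue_maps", hx.ArenaConfig())
    table, counts, props = hx.classify_population(amaps)
    assert sum(counts.values()) == 50
    assert sum(props.values()) == pytest.approx(1.0)
    # mixed fixture battery recovered exactly
    assert list(table["label"]) == labels


def test_all_place_population():
    rng = np.random.default_rng(10)
    values = np.stack([generate_fixture_maps("place", rng)[0] for _ in range(50)])
    amaps = hx.ActivityMaps(values, "cue_maps", hx.ArenaConfig())
    _, counts, _ = hx.classify_population(amaps)
    assert counts["place"] == 50


# -- coverage entropy ------------------------------------------------------

def test_entropy_uniform_single_and_two_bin():
    uniform = np.full((25, 25), 1.0 / 625)
    assert hx.shannon_entropy_bits(uniform) == pytest.approx(9.2877, abs=5e-4)
    single = np.zeros((25, 25))
    single[3, 3] = 1.0
    assert hx.shannon_entropy_bits(single) == 0.0
    two = np.zeros((25, 25))
    two[0, 0] = two[10, 10] = 0.5
    assert hx.shannon_entropy_bits(two) == pytest.approx(1.0)


def test_entropy_bounds_random_maps():
    rng = np.random.default_rng(11)
    for _ in range(20):
        p = rng.random((25, 25)) ** 3
        h = hx.shannon_entropy_bits(p)
        assert 0.0 <= h <= np.log2(625) + 1e-12


def test_coverage_entropy_requires_place_units():
    with pytest.raises(ValueError, match="empty class"):
        hx.coverage_entropy(np.empty((0, 25, 25, 6)))


def test_coverage_entropy_stats():
    rng = np.random.default_rng(12)
    maps = np.stack([generate_fixture_maps("place", rng)[0] for _ in range(5)])
    stats = hx.coverage_entropy(maps, goal_xy=(0.5, 0.5), side_length=2.75)
    assert stats.probabilities.sum() == pytest.approx(1.0)
    assert 0 < stats.entropy_bits < np.log2(625)
    assert stats.field_centers.shape == (5, 2)
    assert stats.mean_center_to_goal_bins is not None


# -- coordinate helpers ----------------------------------------------------

def test_bin_xy_roundtrip():
    side = 2.75
    ij = np.array([[0.0, 0.0], [12.0, 12.0], [24.0, 3.0]])
    back = xy_to_bin(bin_to_xy(ij, side), side)
    assert np.allclose(back, ij)
    # the centre bin maps to the arena centre
    assert np.allclose(bin_to_xy(np.array([12.0, 12.0]), side), [0.0, 0.0])


# -- map computation from a synthetic readout ------------------------------

class RedDetector:
    """Hand-built unit: total red dominance over the image."""

    def features(self, obs):
        obs = np.asarray(obs)
        if obs.ndim == 3:
            obs = obs[None]
        red = (obs[..., 0] - np.maximum(obs[..., 1], obs[..., 2])).clip(min=0)
        return red.sum(axis=(1, 2))[:, None]


def test_cue_maps_of_red_detector_peak_in_view():
    """A unit that responds to red pixels has cue-map mass in front of the
    agent (within the 240-degree FOV), verified via the renderer."""
    arena = hx.ArenaConfig(side_length=2.0, node_spacing=0.5)
    amaps = hx.compute_cue_maps(RedDetector(), arena)
    assert amaps.values.shape == (1, 25, 25, 6)
    m0 = amaps.values[0, :, :, 0]       # heading 0: facing +x
    front = m0[14:, :].sum()
    behind = m0[:11, :].sum()
    assert front > behind
    # rotating the heading rotates the responsive region (heading 3: -x)
    m3 = amaps.values[0, :, :, 3]
    assert m3[:11, :].sum() > m3[14:, :].sum()


def test_position_maps_shape_and_smoothing(small_arena, small_grid):
    spec = hx.NetworkSpec(n_actions=12, conv_filters=(2, 2, 2))
    net = hx.QNetwork(spec, np.random.default_rng(13))
    amaps = hx.compute_position_maps(net, small_arena, small_grid)
    assert amaps.values.shape == (50, 25, 25, 6)
    assert np.all(amaps.values >= 0)


def test_zeroed_network_gives_zero_maps(small_arena, small_grid):
    spec = hx.NetworkSpec(n_actions=12, conv_filters=(2, 2, 2))
    net = hx.QNetwork(spec, np.random.default_rng(14))
    net.params["Wf"][:] = 0.0
    net.params["bf"][:] = 0.0
    amaps = hx.compute_position_maps(net, small_arena, small_grid)
    assert np.all(amaps.values == 0)


def test_maps_hdf5_roundtrip(tmp_path):
    rng = np.random.default_rng(15)
    values = np.stack([generate_fixture_maps("place", rng)[0] for _ in range(3)])
    amaps = hx.ActivityMaps(values, "cue_maps", hx.ArenaConfig())
    path = tmp_path / "maps.h5"
    from hexnav.analysis import load_maps, save_maps
    save_maps(amaps, path)
    back = load_maps(path)
    assert np.allclose(back.values, amaps.values)
    assert back.mode == "cue_maps"
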