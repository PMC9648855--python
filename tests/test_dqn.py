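"""Learner components: dueling head, policy, targets, replay, gradients."""

import numpy as np
import pytest
from scipy import stats

import hexnav as hx
from hexnav.dqn import _batched_targets, dueling_aggregate


@pytest.fixture(scope="module")
def tiny_net():
    spec = hx.NetworkSpec(n_actions=5, conv_filters=(2, 3, 3), dtype=np.float64)
    return hx.QNetwork(spec, np.random.default_rng(0))


# -- dueling aggregation ---------------------------------------------------

def test_dueling_aggregation_identities():
    v = np.array([[2.0]])
    a = np.array([[1.0, 0.0, -1.0]])
    assert np.allclose(dueling_aggregate(v, a), [[3.0, 2.0, 1.0]])
    # constant advantages cancel entirely
    for c in (-3.0, 0.0, 7.5):
        q = dueling_aggregate(np.array([[0.0]]), np.full((1, 4), c))
        assert np.allclose(q, 0.0)
    # adding a constant to all advantages leaves Q unchanged
    rng = np.random.default_rng(1)
    a = rng.normal(size=(3, 6))
    v = rng.normal(size=(3, 1))
    assert np.allclose(dueling_aggregate(v, a), dueling_aggregate(v, a + 4.2))


# -- epsilon-greedy policy -------------------------------------------------

def test_greedy_selection():
    rng = np.random.default_rng(0)
    assert hx.select_action(np.array([1.0, 5.0, 3.0]), 0.0, rng) == 1


def test_full_exploration_uniform():
    """epsilon = 1: empirical action distribution passes chi-square."""
    rng = np.random.default_rng(2)
    q = np.array([0.0, 10.0, 3.0, -2.0])
    counts = np.bincount([hx.select_action(q, 1.0, rng) for _ in range(100000)],
                         minlength=4)
    _, p = stats.chisquare(counts)
    assert p > 0.01


def test_tie_breaking_uniform():
    rng = np.random.default_rng(3)
    q = np.array([2.0, 2.0, 0.0])
    picks = np.array([hx.select_action(q, 0.0, rng) for _ in range(20000)])
    assert set(picks) == {0, 1}
    assert abs((picks == 0).mean() - 0.5) < 0.02


def test_epsilon_fraction_calibrated():
    """Over 1e4+ selections the random-action rate implied by non-greedy
    choices is within +-0.02 of epsilon = 0.3."""
    rng = np.random.default_rng(4)
    n = 12
    q = np.zeros(n)
    q[7] = 10.0                         # unique argmax
    picks = np.array([hx.select_action(q, 0.3, rng) for _ in range(30000)])
    nongreedy = (picks != 7).mean()
    eps_hat = nongreedy * n / (n - 1)
    assert abs(eps_hat - 0.3) < 0.02


# -- TD targets ------------------------------------------------------------

def test_td_target_terminal(tiny_net):
    obs = np.zeros((12, 48, 3))
    assert hx.td_target(1.0, True, obs, tiny_net, tiny_net, 0.99) == 1.0


def test_td_target_double_q_arithmetic(tiny_net):
    """y = r + gamma * Q_target(s', argmax_a Q_online(s',a))."""
    rng = np.random.default_rng(5)
    obs = rng.random((12, 48, 3))
    online = tiny_net
    target = tiny_net.copy()
    # perturb the target head so the two nets disagree
    target.params["Wa"] += 0.5
    a_star = int(np.argmax(online.q_values(obs)))
    expected = -1.0 + 0.99 * target.q_values(obs)[a_star]
    got = hx.td_target(-1.0, False, obs, online, target, 0.99)
    assert got == pytest.approx(expected, rel=1e-6)


def test_double_q_reduces_to_q_learning_when_nets_equal(tiny_net):
    rng = np.random.default_rng(6)
    obs = rng.random((12, 48, 3))
    y = hx.td_target(-1.0, False, obs, tiny_net, tiny_net, 0.9)
    assert y == pytest.approx(-1.0 + 0.9 * tiny_net.q_values(obs).max(), rel=1e-6)


def test_batched_targets_match_single(tiny_net):
    rng = np.random.default_rng(7)
    obs = rng.random((6, 12, 48, 3))
    rewards = rng.choice([-1.0, 1.0], size=6)
    terms = np.array([False, True, False, False, True, False])
    batch = _batched_targets(rewards, terms, obs, tiny_net, tiny_net, 0.99)
    for i in range(6):
        single = hx.td_target(rewards[i], terms[i], obs[i], tiny_net, tiny_net, 0.99)
        assert batch[i] == pytest.approx(single, rel=1e-6)


# -- replay ----------------------------------------------------------------

def test_replay_fifo_capacity():
    buf = hx.ReplayBuffer(capacity=3000, obs_shape=(1,))
    for i in range(5000):
        buf.add(np.array([i]), 0, 0.0, np.array([i]), False)
    assert buf.size == 3000
    stored = set(int(o[0]) for o in buf.obs)
    assert stored == set(range(2000, 5000))     # exactly the most recent 3000


def test_replay_sample_shapes():
    buf = hx.ReplayBuffer(capacity=10)
    rng = np.random.default_rng(0)
    for i in range(4):
        buf.add(np.zeros((12, 48, 3)), i, -1.0, np.zeros((12, 48, 3)), False)
    obs, act, rew, nxt, term = buf.sample(8, rng)
    assert obs.shape == (8, 12, 48, 3) and act.shape == (8,)


# -- network mechanics -----------------------------------------------------

def test_gradients_match_finite_differences(tiny_net):
    """Backprop agrees with central finite differences on every parameter
    block (float64 net)."""
    rng = np.random.default_rng(8)
    x = rng.random((2, 12, 48, 3))
    dq = rng.random((2, 5))
    q, cache = tiny_net.forward(x, return_cache=True)
    grads = tiny_net.backward(cache, dq)

    def loss():
        return float((tiny_net.forward(x) * dq).sum())

    eps = 1e-6
    for k, p in tiny_net.params.items():
        flat_idx = int(np.argmax(np.abs(grads[k])))
        idx = np.unravel_index(flat_idx, p.shape)
        orig = p[idx]
        p[idx] = orig + eps
        lp = loss()
        p[idx] = orig - eps
        lm = loss()
        p[idx] = orig
        num = (lp - lm) / (2 * eps)
        assert grads[k][idx] == pytest.approx(num, rel=1e-5, abs=1e-8)


def test_dropout_only_in_training_mode(tiny_net):
    rng = np.random.default_rng(9)
    x = rng.random((12, 48, 3))
    q1 = tiny_net.forward(x, train=False)
    q2 = tiny_net.forward(x, train=False)
    assert np.array_equal(q1, q2)                        # eval deterministic
    spec = hx.NetworkSpec(n_actions=4, conv_filters=(2, 2, 2),
                          dropout_rate=0.5, dtype=np.float64)
    net = hx.QNetwork(spec, np.random.default_rng(1))
    qa = net.forward(x, train=True, rng=np.random.default_rng(10))
    qb = net.forward(x, train=True, rng=np.random.default_rng(11))
    assert not np.array_equal(qa, qb)                    # dropout stochastic


def test_features_nonnegative_and_50_units():
    spec = hx.NetworkSpec(n_actions=24)
    net = hx.QNetwork(spec, np.random.default_rng(2))
    f = net.features(np.random.default_rng(3).random((12, 48, 3)))
    assert f.shape == (50,)
    assert np.all(f >= 0)


def test_duplicated_copies_distinct_q_same_physics(small_grid):
    """Copies of an egocentric action share physics but have independent
    output weights, so their Q-values generally differ at initialization."""
    space = hx.build_action_space("full", copies=4)
    spec = hx.NetworkSpec(n_actions=24, conv_filters=(4, 4, 4))
    net = hx.QNetwork(spec, np.random.default_rng(4))
    obs = np.random.default_rng(5).random((12, 48, 3))
    q = net.q_values(obs)
    fwd_idx = [i for i, a in enumerate(space.actions) if a.family == "ego_forward"]
    assert len(fwd_idx) == 4
    assert len(set(np.round(q[fwd_idx], 8))) > 1
    pose = hx.Pose(0, 0)
    outs = {(hx.apply_action(pose, space[i], small_grid).new_pose.node,
             hx.apply_action(pose, space[i], small_grid).new_pose.heading)
            for i in fwd_idx}
    assert len(outs) == 1


def test_noise_lesion_locality():
    spec = hx.NetworkSpec(n_actions=6)
    net = hx.QNetwork(spec, np.random.default_rng(6))
    obs = np.random.default_rng(7).random((12, 48, 3))
    targets = np.array([3, 17])
    lesion = hx.NoiseLesion(targets, 2.0, np.random.default_rng(8))
    base = net.features(obs)
    with_lesion = net.features(obs, lesion=lesion)
    # the features accessor reports pre-noise activations: identical
    assert np.array_equal(base, with_lesion)
    # but Q-values are perturbed
    assert not np.array_equal(net.q_values(obs), net.q_values(obs, lesion=lesion))


def test_zero_scale_lesion_is_identity():
    spec = hx.NetworkSpec(n_actions=6)
    net = hx.QNetwork(spec, np.random.default_rng(9))
    obs = np.random.default_rng(10).random((12, 48, 3))
    lesion = hx.NoiseLesion(np.array([0, 1, 2]), 0.0, np.random.default_rng(11))
    assert np.array_equal(net.q_values(obs), net.q_values(obs, lesion=lesion))


def test_save_load_roundtrip(tmp_path, tiny_net):
    path = tmp_path / "net.npz"
    tiny_net.save(path)
    back = hx.QNetwork.load(path, tiny_net.spec)
    obs = np.random.default_rng(12).random((12, 48, 3))
    assert np.allclose(tiny_net.q_values(obs), back.q_values(obs))


def test_mismatched_action_space_rejected(small_arena):
    env = hx.NavEnv(small_arena, hx.build_action_space("egocentric"),
                    hx.EpisodeConfig(task="guidance"))
    spec = hx.NetworkSpec(n_actions=24, conv_filters=(2, 2, 2))
    with pytest.raises(ValueError, match="mismatch"):
        hx.train(env, spec, hx.HyperParams(n_trials=1), rng_seed=0)
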