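"""Convolutional dueling double-DQN, trained by TD learning with experience
replay and epsilon-greedy exploration.

The network maps a 12x48x3 panoramic observation to one Q-value per action:
three 5x5 convolutions (32, 64, 64 filters by default), a fully connected
layer of 50 rectified units — the *analysis layer* whose spatial tuning the
rest of the pipeline classifies — with dropout during training, and a dueling
head: a scalar state value V(s) and per-action advantages A(s,a), combined as

    Q(s,a) = V(s) + A(s,a) - mean_a' A(s,a')

Learning follows one-step Q-learning with the double-Q target

    y = r                                              (terminal)
    y = r + gamma * Q_target(s', argmax_a Q_online(s', a))   (otherwise)

minimising the squared TD error of the chosen action only (so with duplicated
egocentric actions, credit flows only to the copy that was picked).  All
linear algebra is plain numpy; convolutions are evaluated as 25 shifted
slice/contract pairs, which is fast at this input size.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rendering import IMG_H, IMG_W

# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class NetworkSpec:
    n_actions: int
    conv_filters: tuple = (32, 64, 64)
    kernel: tuple = (5, 5)
    #: per-layer (row, col) strides / paddings; the defaults shrink 12x48 to
    #: a 2x3 map after three 5x5 layers (stride 2 along the panorama axis)
    conv_strides: tuple = ((1, 2), (1, 2), (1, 2))
    conv_pads: tuple = ((0, 0), (0, 0), (1, 0))
    fc_units: int = 50
    dropout_rate: float = 0.35
    dueling: bool = True
    dtype: type = np.float32


@dataclass
class HyperParams:
    learning_rate: float = 0.001
    gamma: float = 0.99
    epsilon: float = 0.3           # constant throughout training
    replay_capacity: int = 3000
    n_trials: int = 4000
    batch_size: int = 32
    target_sync_interval: int = 100   # environment steps between target syncs
    train_every: int = 1              # gradient steps per this many env steps


# ---------------------------------------------------------------------------
# Conv primitives
# ---------------------------------------------------------------------------

def _conv_forward(x, W, b, stride, pad):
    """x: (N,C,H,Wd); W: (F,C,KH,KW) -> (out (N,F,Ho,Wo), im2col cache).

    The convolution is lowered to one GEMM per layer: patches are gathered
    into columns (KH*KW slice copies) and contracted against the reshaped
    filter bank, which is the fastest numpy formulation at this input size.
    """
    sh, sw = stride
    ph, pw = pad
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    N, C, H, Wd = x.shape
    F, _, KH, KW = W.shape
    Ho = (H - KH) // sh + 1
    Wo = (Wd - KW) // sw + 1
    cols = np.empty((N, C, KH, KW, Ho, Wo), dtype=x.dtype)
    for ki in range(KH):
        for kj in range(KW):
            cols[:, :, ki, kj] = x[:, :, ki:ki + sh * Ho:sh, kj:kj + sw * Wo:sw]
    cols = cols.reshape(N, C * KH * KW, Ho * Wo)
    out = np.matmul(W.reshape(F, -1), cols).reshape(N, F, Ho, Wo)
    out += b[None, :, None, None]
    return out, (cols, x.shape, (Ho, Wo))


def _conv_backward(dout, cache, W, stride, pad, in_shape):
    cols, pad_shape, (Ho, Wo) = cache
    sh, sw = stride
    ph, pw = pad
    F, C, KH, KW = W.shape
    N = dout.shape[0]
    dmat = dout.reshape(N, F, Ho * Wo)
    dW = np.tensordot(dmat, cols, axes=([0, 2], [0, 2])).reshape(W.shape)
    db = dout.sum(axis=(0, 2, 3))
    dcols = np.matmul(W.reshape(F, -1).T, dmat).reshape(N, C, KH, KW, Ho, Wo)
    dx = np.zeros(pad_shape, dtype=dout.dtype)
    for ki in range(KH):
        for kj in range(KW):
            dx[:, :, ki:ki + sh * Ho:sh, kj:kj + sw * Wo:sw] += dcols[:, :, ki, kj]
    if ph or pw:
        H, Wd = in_shape
        dx = dx[:, :, ph:ph + H, pw:pw + Wd]
    return dx, dW, db


def dueling_aggregate(v, a):
    """Q(s,a) = V(s) + A(s,a) - mean_a A(s,a); v (N,1), a (N,K)."""
    return v + a - a.mean(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Lesion hook
# ---------------------------------------------------------------------------

@dataclass
class NoiseLesion:
    """Additive Gaussian noise on selected analysis-layer units.

    The noise s.d. is ``scale`` times the maximum activation in the layer —
    by default the per-forward-pass maximum over the 50 units (set
    ``layer_max`` to a constant for a dataset-wide reference instead).
    Noise is redrawn independently on every forward pass.
    """

    targets: np.ndarray
    scale: float
    rng: np.random.Generator
    layer_max: float | None = None

    def apply(self, h):
        if self.scale == 0.0 or len(self.targets) == 0:
            return h
        if self.layer_max is None:
            ref = h.max(axis=1, keepdims=True)            # per-pass maximum
        else:
            ref = np.full((h.shape[0], 1), float(self.layer_max))
        noise = self.rng.standard_normal((h.shape[0], len(self.targets)))
        h = h.copy()
        h[:, self.targets] += self.scale * ref * noise
        return h


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

class QNetwork:
    """Parameters plus forward/backward passes; no autograd framework."""

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator):
        self.spec = spec
        dt = spec.dtype
        self.params: dict[str, np.ndarray] = {}
        c_in = 3
        h, w = IMG_H, IMG_W
        for i, f in enumerate(spec.conv_filters):
            kh, kw = spec.kernel
            fan_in = c_in * kh * kw
            self.params[f"Wc{i}"] = (rng.standard_normal((f, c_in, kh, kw))
                                     * np.sqrt(2.0 / fan_in)).astype(dt)
            self.params[f"bc{i}"] = np.zeros(f, dtype=dt)
            (sh, sw), (ph, pw) = spec.conv_strides[i], spec.conv_pads[i]
            h = (h + 2 * ph - kh) // sh + 1
            w = (w + 2 * pw - kw) // sw + 1
            c_in = f
        self.flat_dim = c_in * h * w
        nf = spec.fc_units
        self.params["Wf"] = (rng.standard_normal((self.flat_dim, nf))
                             * np.sqrt(2.0 / self.flat_dim)).astype(dt)
        self.params["bf"] = np.zeros(nf, dtype=dt)
        if spec.dueling:
            self.params["Wv"] = (rng.standard_normal((nf, 1))
                                 * np.sqrt(1.0 / nf)).astype(dt)
            self.params["bv"] = np.zeros(1, dtype=dt)
        self.params["Wa"] = (rng.standard_normal((nf, spec.n_actions))
                             * np.sqrt(1.0 / nf)).astype(dt)
        self.params["ba"] = np.zeros(spec.n_actions, dtype=dt)

    # -- inference ---------------------------------------------------------
    def forward(self, obs, train: bool = False, rng=None, lesion=None,
                return_cache: bool = False):
        """Q-values for a batch of observations (N,12,48,3) or one (12,48,3).

        ``train=True`` activates dropout on the analysis layer (requires
        ``rng``); evaluation passes are deterministic.  ``lesion`` is a
        :class:`NoiseLesion` applied to the post-rectifier analysis-layer
        activations (the cache keeps the pre-noise activations).
        """
        single = obs.ndim == 3
        x = np.asarray(obs, dtype=self.spec.dtype)
        if single:
            x = x[None]
        x = np.moveaxis(x, 3, 1)        # NHWC -> NCHW
        cache = {"conv": []}
        for i in range(len(self.spec.conv_filters)):
            z, conv_cache = _conv_forward(x, self.params[f"Wc{i}"], self.params[f"bc{i}"],
                                          self.spec.conv_strides[i], self.spec.conv_pads[i])
            cache["conv"].append((conv_cache, z, x.shape[2:]))
            x = np.maximum(z, 0.0)
        flat = x.reshape(x.shape[0], -1)
        zf = flat @ self.params["Wf"] + self.params["bf"]
        hf = np.maximum(zf, 0.0)
        cache["features"] = hf           # pre-dropout, pre-noise activations
        if train and self.spec.dropout_rate > 0.0:
            keep = 1.0 - self.spec.dropout_rate
            mask = (rng.random(hf.shape) < keep) / keep
            h = hf * mask
            cache["drop_mask"] = mask
        else:
            h = hf
            cache["drop_mask"] = None
        if lesion is not None:
            h = lesion.apply(h)
        adv = h @ self.params["Wa"] + self.params["ba"]
        if self.spec.dueling:
            v = h @ self.params["Wv"] + self.params["bv"]
            q = dueling_aggregate(v, adv)
        else:
            q = adv
        cache.update(flat=flat, zf=zf, h=h)
        if single:
            q = q[0]
        return (q, cache) if return_cache else q

    def q_values(self, obs, lesion=None):
        """Evaluation-mode Q-values (dropout off)."""
        return self.forward(obs, train=False, lesion=lesion)

    def features(self, obs, lesion=None):
        """Analysis-layer activations (50 rectified units), evaluation mode.

        Returns the pre-noise activations; pass ``lesion`` only to check
        perturbation locality downstream of the hook.
        """
        _, cache = self.forward(obs, train=False, lesion=lesion, return_cache=True)
        f = cache["features"]
        return f[0] if np.asarray(obs).ndim == 3 else f

    # -- learning ----------------------------------------------------------
    def backward(self, cache, dq):
        """Gradient of a scalar loss wrt parameters, given dL/dQ (N,K)."""
        g = {}
        h = cache["h"]
        if self.spec.dueling:
            # Q = V + A - mean(A): dQ_k/dV = 1, dQ_k/dA_j = delta_kj - 1/K
            dv = dq.sum(axis=1, keepdims=True)
            da = dq - dv / dq.shape[1]
            g["Wv"] = h.T @ dv
            g["bv"] = dv.sum(axis=0)
            g["Wa"] = h.T @ da
            g["ba"] = da.sum(axis=0)
            dh = dv @ self.params["Wv"].T + da @ self.params["Wa"].T
        else:
            g["Wa"] = h.T @ dq
            g["ba"] = dq.sum(axis=0)
            dh = dq @ self.params["Wa"].T
        if cache["drop_mask"] is not None:
            dh = dh * cache["drop_mask"]
        dzf = dh * (cache["zf"] > 0)
        g["Wf"] = cache["flat"].T @ dzf
        g["bf"] = dzf.sum(axis=0)
        dflat = dzf @ self.params["Wf"].T

        dx = dflat.reshape(-1, *self._conv_out_shape())
        for i in reversed(range(len(self.spec.conv_filters))):
            conv_cache, z, in_shape = cache["conv"][i]
            dx = dx * (z > 0)
            dx, dW, db = _conv_backward(dx, conv_cache, self.params[f"Wc{i}"],
                                        self.spec.conv_strides[i],
                                        self.spec.conv_pads[i], in_shape)
            g[f"Wc{i}"] = dW
            g[f"bc{i}"] = db
        return g

    def _conv_out_shape(self):
        h, w = IMG_H, IMG_W
        kh, kw = self.spec.kernel
        for i in range(len(self.spec.conv_filters)):
            (sh, sw), (ph, pw) = self.spec.conv_strides[i], self.spec.conv_pads[i]
            h = (h + 2 * ph - kh) // sh + 1
            w = (w + 2 * pw - kw) // sw + 1
        return (self.spec.conv_filters[-1], h, w)

    def copy(self) -> "QNetwork":
        dup = object.__new__(QNetwork)
        dup.spec = self.spec
        dup.flat_dim = self.flat_dim
        dup.params = {k: v.copy() for k, v in self.params.items()}
        return dup

    def load_from(self, other: "QNetwork"):
        for k in self.params:
            np.copyto(self.params[k], other.params[k])

    # -- persistence -------------------------------------------------------
    def save(self, path):
        np.savez(path, **self.params,
                 _meta=np.array([self.spec.n_actions, self.spec.fc_units]))

    @classmethod
    def load(cls, path, spec: NetworkSpec):
        data = np.load(path)
        rng = np.random.default_rng(0)
        net = cls(spec, rng)
        for k in net.params:
            net.params[k] = data[k].astype(spec.dtype)
        return net


class Adam:
    """Adaptive-moment optimizer (the configurable default)."""

    def __init__(self, params, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for k, gr in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * gr
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * gr * gr
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


# ---------------------------------------------------------------------------
# Replay, policy, targets
# ---------------------------------------------------------------------------

class ReplayBuffer:
    """Strictly FIFO, capacity-bounded transition store."""

    def __init__(self, capacity: int, obs_shape=(IMG_H, IMG_W, 3)):
        self.capacity = capacity
        self.obs = np.empty((capacity, *obs_shape), dtype=np.float32)
        self.next_obs = np.empty((capacity, *obs_shape), dtype=np.float32)
        self.actions = np.empty(capacity, dtype=np.int64)
        self.rewards = np.empty(capacity, dtype=np.float64)
        self.terminal = np.empty(capacity, dtype=bool)
        self._next = 0
        self.size = 0
        self.total_added = 0

    def add(self, obs, action, reward, next_obs, terminal):
        i = self._next
        self.obs[i] = obs
        self.next_obs[i] = next_obs
        self.actions[i] = action
        self.rewards[i] = reward
        self.terminal[i] = terminal
        self._next = (i + 1) % self.capacity
        self.size = min(self.size + 1, self.capacity)
        self.total_added += 1

    def sample(self, batch_size: int, rng: np.random.Generator):
        idx = rng.integers(self.size, size=batch_size)
        return (self.obs[idx], self.actions[idx], self.rewards[idx],
                self.next_obs[idx], self.terminal[idx])


def select_action(q, epsilon: float, rng: np.random.Generator) -> int:
    """Epsilon-greedy with uniform random tie-breaking among exact maxima."""
    q = np.asarray(q)
    if rng.random() < epsilon:
        return int(rng.integers(len(q)))
    ties = np.flatnonzero(q == q.max())
    return int(ties[0]) if len(ties) == 1 else int(rng.choice(ties))


def td_target(reward, terminal, next_obs, online_net, target_net, gamma):
    """Double-Q one-step target for a single transition."""
    if terminal:
        return float(reward)
    q_online = online_net.q_values(next_obs)
    a_star = int(np.argmax(q_online))
    q_target = target_net.q_values(next_obs)
    return float(reward + gamma * q_target[a_star])


def _batched_targets(rewards, terminals, next_obs, online_net, target_net, gamma):
    q_online = online_net.q_values(next_obs)
    a_star = np.argmax(q_online, axis=1)
    q_target = target_net.q_values(next_obs)
    boot = q_target[np.arange(len(a_star)), a_star]
    return rewards + gamma * np.where(terminals, 0.0, boot)


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    network: QNetwork
    curve: pd.DataFrame          # trial, total_reward, steps, success, frac_allocentric
    hyper: HyperParams
    spec: NetworkSpec
    step_log: pd.DataFrame | None = None   # per-step log when requested


def train(env, spec: NetworkSpec | None, hyper: HyperParams,
          rng_seed: int, phase: str = "train",
          checkpoint_hook=None, checkpoint_every: int | None = None,
          log_steps: bool = False) -> TrainResult:
    """Run the full training protocol on ``env``.

    Every transition goes into the FIFO replay buffer; once the buffer can
    fill a minibatch, each ``train_every``-th environment step samples a
    uniform minibatch and takes one Adam step on the squared TD error of the
    chosen actions (double-Q targets, target net synced every
    ``target_sync_interval`` steps).  Returns the trained network and the
    per-episode learning curve, including the fraction of chosen actions
    that were allocentric.

    Raises
    ------
    RuntimeError
        If the TD loss becomes non-finite (divergence).
    """
    rng = np.random.default_rng(rng_seed)
    if spec is None:
        spec = NetworkSpec(n_actions=env.n_actions)
    if spec.n_actions != env.n_actions:
        raise ValueError("network/action-space size mismatch")
    net = QNetwork(spec, rng)
    target = net.copy()
    opt = Adam(net.params, lr=hyper.learning_rate)
    buf = ReplayBuffer(hyper.replay_capacity)
    allo_mask = np.array(env.action_space.allocentric_mask())

    records = []
    step_rows = []
    global_step = 0
    for trial in range(hyper.n_trials):
        obs = env.reset(phase=phase, rng=rng)
        total_r, steps, n_allo = 0.0, 0, 0
        terminal = False
        while not terminal:
            q = net.q_values(obs)
            a = select_action(q, hyper.epsilon, rng)
            tr = env.step(a)
            buf.add(tr.observation, a, tr.reward, tr.next_observation, tr.terminal)
            obs, terminal = tr.next_observation, tr.terminal
            total_r += tr.reward
            steps += 1
            n_allo += int(allo_mask[a])
            if log_steps:
                step_rows.append((trial, steps, env.pose.node, env.pose.heading,
                                  a, tr.reward, tr.terminal))
            global_step += 1

            if buf.size >= hyper.batch_size and global_step % hyper.train_every == 0:
                b_obs, b_act, b_rew, b_next, b_term = buf.sample(hyper.batch_size, rng)
                y = _batched_targets(b_rew, b_term, b_next, net, target, hyper.gamma)
                qb, cache = net.forward(b_obs, train=True, rng=rng, return_cache=True)
                chosen = qb[np.arange(len(b_act)), b_act]
                err = chosen - y
                loss = float(np.mean(err ** 2))
                if not np.isfinite(loss):
                    raise RuntimeError(f"divergence: non-finite TD loss at step {global_step}")
                dq = np.zeros_like(qb)
                dq[np.arange(len(b_act)), b_act] = 2.0 * err / len(b_act)
                grads = net.backward(cache, dq)
                opt.step(net.params, grads)
            if global_step % hyper.target_sync_interval == 0:
                target.load_from(net)

        records.append((trial, total_r, steps, env.last_success, n_allo / steps))
        if checkpoint_hook is not None and checkpoint_every \
                and (trial + 1) % checkpoint_every == 0:
            checkpoint_hook(trial + 1, net)

    curve = pd.DataFrame(records, columns=[
        "trial", "total_reward", "steps", "success", "frac_allocentric"])
    step_log = pd.DataFrame(step_rows, columns=[
        "trial", "step", "node", "heading", "action_index", "reward",
        "terminal"]) if log_steps else None
    return TrainResult(net, curve, hyper, spec, step_log)


def evaluate(net: QNetwork, env, n_trials: int, rng_seed: int,
             epsilon: float = 0.05, lesion: NoiseLesion | None = None,
             phase: str = "train"):
    """Test-phase evaluation at a small exploration rate (0.05, the customary
    DQN test-phase epsilon: a purely greedy policy can trap a deterministic
    agent in a rotation loop); returns (success_fraction, per-trial step
    counts).  Environment randomness is driven solely by ``rng_seed`` so runs
    with identical seeds see identical trials."""
    rng = np.random.default_rng(rng_seed)
    successes, steps_list = 0, []
    for _ in range(n_trials):
        obs = env.reset(phase=phase, rng=rng)
        terminal, steps = False, 0
        while not terminal:
            q = net.q_values(obs, lesion=lesion)
            a = select_action(q, epsilon, rng)
            tr = env.step(a)
            obs, terminal = tr.next_observation, tr.terminal
            steps += 1
        successes += int(env.last_success)
        steps_list.append(steps)
    return successes / n_trials, steps_list
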