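"""Soft Actor-Critic for discrete action spaces.

The agent keeps a categorical policy pi_phi and twin soft Q-functions
Q_theta1, Q_theta2 (with Polyak-averaged target copies), all small dense
networks over the flattened board observation. Against a replay buffer
of transitions it alternates:

* soft Q targets with the clipped double-Q trick,
      y = r + gamma (1 - done) * V(s'),
      V(s') = pi(s')^T [ min_i Qbar_i(s') - alpha log pi(s') ]
* one Adam step per Q-network on the squared error to y,
* one Adam step on the policy objective
      E_s [ pi(s)^T ( alpha log pi(s) - min_i Q_i(s) ) ],
* target update thetabar <- tau thetabar + (1 - tau) theta.

The entropy temperature alpha weighs exploration against reward; as
alpha -> 0 the objective reduces to the standard expected return. alpha
is held fixed between population-based-training events (see
:mod:`copsense.pbt`) rather than autotuned by gradient.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from ._nn import MLP, Adam

__all__ = [
    "SACConfig",
    "AgentNetworks",
    "ReplayBuffer",
    "Transition",
    "SACAgent",
    "policy_distribution",
    "soft_state_value",
    "q_target",
    "update_q",
    "update_policy",
    "polyak_update",
    "train",
]

_LOGP_FLOOR = 1e-8  # probability clamp inside logs, makes 0*log0 = 0 exact


@dataclass
class SACConfig:
    gamma: float = 0.99
    tau: float = 0.995  # target <- tau*target + (1-tau)*local
    alpha: float = 4e-3
    lr: float = 3e-4
    batch_size: int = 64
    update_every: int = 4  # agent steps between gradient updates
    grad_steps: int = 1  # gradient updates per cadence tick
    buffer_capacity: int = 100_000
    warmup_steps: int = 1_000  # uniform-random action steps before learning
    hidden_sizes: tuple[int, ...] = (64, 64)
    skip_connections: bool = True  # linear input->output shortcut per head
    obs_scale: float = 1.0  # observation multiplier (e.g. 1/n_sensors)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError("tau must be in [0, 1]")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        for name in ("lr", "batch_size", "update_every", "buffer_capacity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class Transition:
    s: np.ndarray
    a: int
    r: float
    s_next: np.ndarray
    done: bool


class ReplayBuffer:
    """FIFO transition store with uniform without-replacement batches."""

    def __init__(self, capacity: int, obs_dim: int, rng: np.random.Generator):
        self.capacity = capacity
        self._s = np.zeros((capacity, obs_dim), dtype=np.float32)
        self._a = np.zeros(capacity, dtype=np.int64)
        self._r = np.zeros(capacity, dtype=np.float64)
        self._s2 = np.zeros((capacity, obs_dim), dtype=np.float32)
        self._done = np.zeros(capacity, dtype=np.float64)
        self._rng = rng
        self._next = 0
        self.size = 0

    def add(self, t: Transition) -> None:
        i = self._next
        self._s[i] = t.s
        self._a[i] = t.a
        self._r[i] = t.r
        self._s2[i] = t.s_next
        self._done[i] = float(t.done)
        self._next = (i + 1) % self.capacity
        self.size = min(self.size + 1, self.capacity)

    def sample(self, batch_size: int) -> dict[str, np.ndarray]:
        if batch_size > self.size:
            raise ValueError("not enough transitions to sample a batch")
        idx = self._rng.choice(self.size, size=batch_size, replace=False)
        return {
            "s": self._s[idx].astype(np.float64),
            "a": self._a[idx],
            "r": self._r[idx],
            "s_next": self._s2[idx].astype(np.float64),
            "done": self._done[idx],
        }


class AgentNetworks:
    """Policy, twin Q-networks, their targets and optimizers."""

    def __init__(
        self,
        obs_dim: int,
        n_actions: int,
        config: SACConfig,
        rng: np.random.Generator,
    ):
        self.obs_dim = obs_dim
        self.n_actions = n_actions
        self.obs_scale = config.obs_scale
        hidden = list(config.hidden_sizes)
        skip = config.skip_connections
        self.policy = MLP(obs_dim, hidden, n_actions, rng, skip=skip)
        self.q1 = MLP(obs_dim, hidden, n_actions, rng, skip=skip)
        self.q2 = MLP(obs_dim, hidden, n_actions, rng, skip=skip)
        self.q1_target = self.q1.copy()
        self.q2_target = self.q2.copy()
        self.opt_policy = Adam(self.policy.parameters(), lr=config.lr)
        self.opt_q1 = Adam(self.q1.parameters(), lr=config.lr)
        self.opt_q2 = Adam(self.q2.parameters(), lr=config.lr)

    def features(self, states: np.ndarray) -> np.ndarray:
        """Flatten and scale observations into network inputs."""
        x = np.asarray(states, dtype=float).reshape(-1, self.obs_dim)
        return x * self.obs_scale

    def copy_from(self, other: "AgentNetworks") -> None:
        """Adopt another agent's parameters and optimizer state."""
        for name in ("policy", "q1", "q2", "q1_target", "q2_target"):
            getattr(self, name).set_parameters(getattr(other, name).parameters())
        for name in ("opt_policy", "opt_q1", "opt_q2"):
            getattr(self, name).load_state(getattr(other, name).state())


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def policy_distribution(networks: AgentNetworks, state: np.ndarray) -> np.ndarray:
    """Action probabilities for one state; non-negative, sum to 1."""
    logits = networks.policy.forward(networks.features(state))
    if not np.isfinite(logits).all():
        raise FloatingPointError("non-finite policy logits")
    return _softmax(logits)[0]


def soft_state_value(
    probs: np.ndarray, q_values: np.ndarray, alpha: float
) -> np.ndarray:
    """V = pi^T (Q - alpha log pi), elementwise over a batch."""
    logp = np.log(np.clip(probs, _LOGP_FLOOR, None))
    return np.sum(probs * (q_values - alpha * logp), axis=-1)


def q_target(
    r: np.ndarray,
    s_next: np.ndarray,
    done: np.ndarray,
    networks: AgentNetworks,
    config: SACConfig,
) -> np.ndarray:
    """Soft Q targets y = r + gamma(1-done) V(s') with clipped double-Q."""
    x = networks.features(s_next)
    probs = _softmax(networks.policy.forward(x))
    q_min = np.minimum(
        networks.q1_target.forward(x), networks.q2_target.forward(x)
    )
    v = soft_state_value(probs, q_min, config.alpha)
    return r + config.gamma * (1.0 - done) * v


def update_q(
    networks: AgentNetworks, batch: dict[str, np.ndarray], config: SACConfig
) -> tuple[float, float]:
    """One Adam step per Q-network on the squared error to the soft target."""
    y = q_target(batch["r"], batch["s_next"], batch["done"], networks, config)
    x = networks.features(batch["s"])
    a = batch["a"]
    n = len(a)
    losses = []
    for net, opt in ((networks.q1, networks.opt_q1), (networks.q2, networks.opt_q2)):
        cache: list = []
        q = net.forward(x, cache)
        err = q[np.arange(n), a] - y
        losses.append(float(np.mean(err**2)))
        dout = np.zeros_like(q)
        dout[np.arange(n), a] = 2.0 * err / n
        opt.step(net.parameters(), net.backward(cache, dout))
    return losses[0], losses[1]


def update_policy(
    networks: AgentNetworks, batch: dict[str, np.ndarray], config: SACConfig
) -> float:
    """One Adam step on E_s[ pi^T (alpha log pi - min_i Q_i) ]; Q frozen."""
    x = networks.features(batch["s"])
    n = x.shape[0]
    q_min = np.minimum(networks.q1.forward(x), networks.q2.forward(x))
    cache: list = []
    logits = networks.policy.forward(x, cache)
    probs = _softmax(logits)
    logp = np.log(np.clip(probs, _LOGP_FLOOR, None))
    inner = config.alpha * logp - q_min
    loss = float(np.mean(np.sum(probs * inner, axis=1)))
    # d/dlogits of p^T g with g = alpha(log p + 1) - q_min, p = softmax(logits)
    g = config.alpha * (logp + 1.0) - q_min
    dlogits = probs * (g - np.sum(probs * g, axis=1, keepdims=True)) / n
    networks.opt_policy.step(
        networks.policy.parameters(), networks.policy.backward(cache, dlogits)
    )
    return loss


def polyak_update(networks: AgentNetworks, tau: float) -> None:
    """thetabar <- tau thetabar + (1 - tau) theta for both Q targets."""
    networks.q1_target.polyak_toward(networks.q1, tau)
    networks.q2_target.polyak_toward(networks.q2, tau)


class SACAgent:
    """Ties networks, buffer and an environment into a training loop.

    The environment must expose ``n_actions``, ``observation_shape``,
    ``seed``, ``reset() -> obs`` and ``step(a) -> (obs, reward, done)``.
    All randomness (network init, action sampling, batch sampling, the
    environment's episode draws) derives from ``config.seed``.
    """

    def __init__(self, env, config: SACConfig):
        self.env = env
        self.config = config
        ss = np.random.SeedSequence(config.seed)
        s_init, s_act, s_buf, s_env = ss.spawn(4)
        self.networks = AgentNetworks(
            int(np.prod(env.observation_shape)),
            env.n_actions,
            config,
            np.random.default_rng(s_init),
        )
        self._act_rng = np.random.default_rng(s_act)
        self.buffer = ReplayBuffer(
            config.buffer_capacity,
            int(np.prod(env.observation_shape)),
            np.random.default_rng(s_buf),
        )
        env.seed(int(s_env.generate_state(1)[0] % (2**31)))
        self.total_steps = 0
        self.episode_log: list[dict] = []
        self._obs: np.ndarray | None = None
        self._episode_return = 0.0

    # -- acting ------------------------------------------------------------

    def act(self, obs: np.ndarray, greedy: bool = False) -> int:
        probs = policy_distribution(self.networks, obs)
        if greedy:
            return int(np.argmax(probs))
        return int(self._act_rng.choice(len(probs), p=probs))

    # -- training ----------------------------------------------------------

    def train_steps(self, n_steps: int) -> None:
        cfg = self.config
        if self._obs is None:
            self._obs = self.env.reset()
            self._episode_return = 0.0
        for _ in range(n_steps):
            if self.total_steps < cfg.warmup_steps:
                action = int(self._act_rng.integers(self.env.n_actions))
            else:
                action = self.act(self._obs)
            obs_next, reward, done = self.env.step(action)
            self.buffer.add(
                Transition(
                    np.asarray(self._obs, dtype=float).ravel(),
                    action,
                    reward,
                    np.asarray(obs_next, dtype=float).ravel(),
                    done,
                )
            )
            self.total_steps += 1
            self._episode_return += reward
            if done:
                self.episode_log.append(
                    {
                        "episode": len(self.episode_log),
                        "reward": self._episode_return,
                        "alpha": cfg.alpha,
                        "steps": self.total_steps,
                    }
                )
                self._obs = self.env.reset()
                self._episode_return = 0.0
            else:
                self._obs = obs_next
            if (
                self.total_steps >= cfg.warmup_steps
                and self.total_steps % cfg.update_every == 0
                and self.buffer.size >= cfg.batch_size
            ):
                for _ in range(cfg.grad_steps):
                    batch = self.buffer.sample(cfg.batch_size)
                    update_q(self.networks, batch, cfg)
                    update_policy(self.networks, batch, cfg)
                    polyak_update(self.networks, cfg.tau)

    def episode_rewards(self) -> list[float]:
        return [e["reward"] for e in self.episode_log]

    def greedy_rollout(self) -> tuple[list[int], float]:
        """Run one episode taking argmax-probability actions.

        Returns the action sequence and the sum of environment rewards,
        which in either reward mode equals the terminal episode reward
        of the final placement.
        """
        obs = self.env.reset()
        actions: list[int] = []
        total = 0.0
        done = False
        while not done:
            a = self.act(obs, greedy=True)
            obs, r, done = self.env.step(a)
            actions.append(a)
            total += r
        # the evaluation episode consumed the environment; restart training
        # from a fresh episode (any interrupted episode is discarded)
        self._obs = self.env.reset()
        self._episode_return = 0.0
        return actions, total

    # -- checkpointing -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Self-describing checkpoint: architecture, parameters, optimizer
        and RNG states (numpy archive)."""
        arrays: dict[str, np.ndarray] = {}
        for name in ("policy", "q1", "q2", "q1_target", "q2_target"):
            for i, p in enumerate(getattr(self.networks, name).parameters()):
                arrays[f"{name}/{i}"] = p
        for name in ("opt_policy", "opt_q1", "opt_q2"):
            st = getattr(self.networks, name).state()
            for i, (m, v) in enumerate(zip(st["m"], st["v"])):
                arrays[f"{name}/m{i}"] = m
                arrays[f"{name}/v{i}"] = v
            arrays[f"{name}/t"] = np.array(st["t"])
        meta = {
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self.config).items()
            },
            "total_steps": self.total_steps,
            "act_rng": self._act_rng.bit_generator.state,
            "buf_rng": self.buffer._rng.bit_generator.state,
            "episode_log": self.episode_log,
        }
        arrays["meta"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8
        ).copy()
        np.savez(path, **arrays)

    def load(self, path: str | Path) -> None:
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            for name in ("policy", "q1", "q2", "q1_target", "q2_target"):
                net = getattr(self.networks, name)
                net.set_parameters(
                    [data[f"{name}/{i}"] for i in range(len(net.parameters()))]
                )
            for name in ("opt_policy", "opt_q1", "opt_q2"):
                opt = getattr(self.networks, name)
                k = len(opt.m)
                opt.load_state(
                    {
                        "m": [data[f"{name}/m{i}"] for i in range(k)],
                        "v": [data[f"{name}/v{i}"] for i in range(k)],
                        "t": int(data[f"{name}/t"]),
                    }
                )
        self.total_steps = meta["total_steps"]
        self.episode_log = meta["episode_log"]
        self._act_rng.bit_generator.state = meta["act_rng"]
        self.buffer._rng.bit_generator.state = meta["buf_rng"]


def train(env, config: SACConfig, budget: int) -> tuple[SACAgent, list[dict]]:
    """Train a fresh agent for ``budget`` agent steps; returns it with its
    per-episode reward log."""
    if budget < 0:
        raise ValueError("budget must be >= 0")
    agent = SACAgent(env, config)
    agent.train_steps(budget)
    return agent, agent.episode_log
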