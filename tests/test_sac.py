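"""SAC-Discrete components: distributions, targets, updates, training loop."""

import numpy as np
import pytest

from copsense.sac import (
    AgentNetworks,
    ReplayBuffer,
    SACAgent,
    SACConfig,
    Transition,
    policy_distribution,
    polyak_update,
    q_target,
    soft_state_value,
    train,
    update_policy,
    update_q,
)


class BanditEnv:
    """One-state, k-armed, one-step environment with fixed rewards."""

    def __init__(self, rewards):
        self.rewards = list(rewards)
        self.n_actions = len(self.rewards)
        self.observation_shape = (1,)

    def seed(self, seed):
        pass

    def reset(self):
        return np.zeros(1)

    def step(self, a):
        return np.zeros(1), float(self.rewards[a]), True


def small_networks(n_actions=4, obs_dim=3, alpha=1.0, seed=0, hidden=(16,)):
    cfg = SACConfig(alpha=alpha, seed=seed, hidden_sizes=hidden)
    return AgentNetworks(obs_dim, n_actions, cfg, np.random.default_rng(seed)), cfg


class TestPolicyDistribution:
    def test_valid_distribution(self, rng):
        nets, _ = small_networks()
        p = policy_distribution(nets, rng.normal(size=3))
        assert np.all(p >= 0)
        assert p.sum() == pytest.approx(1.0, abs=1e-6)

    def test_zeroed_final_layer_gives_uniform(self, rng):
        nets, _ = small_networks(n_actions=5)
        nets.policy.W[-1][:] = 0.0
        nets.policy.b[-1][:] = 0.0
        p = policy_distribution(nets, rng.normal(size=3))
        assert np.allclose(p, 0.2)

    def test_nonfinite_logits_rejected(self):
        nets, _ = small_networks()
        nets.policy.W[0][:] = np.inf
        with np.errstate(invalid="ignore"), pytest.raises(FloatingPointError):
            policy_distribution(nets, np.ones(3))

    def test_seeded_sampling_reproducible(self):
        env = BanditEnv([0.0, 1.0, 0.5])
        a1 = SACAgent(env, SACConfig(seed=9, hidden_sizes=(8,)))
        a2 = SACAgent(env, SACConfig(seed=9, hidden_sizes=(8,)))
        obs = env.reset()
        assert [a1.act(obs) for _ in range(20)] == [a2.act(obs) for _ in range(20)]


class TestSoftStateValue:
    def test_uniform_binary_entropy(self):
        v = soft_state_value(np.array([0.5, 0.5]), np.array([0.0, 0.0]), alpha=1.0)
        assert v == pytest.approx(np.log(2.0), abs=1e-12)

    def test_alpha_zero_constant_q(self):
        v = soft_state_value(np.array([0.3, 0.7]), np.array([2.5, 2.5]), alpha=0.0)
        assert v == pytest.approx(2.5)

    def test_degenerate_policy_zero_entropy(self):
        # clamp makes 0 * log 0 contribute ~0
        v = soft_state_value(np.array([1.0, 0.0]), np.array([3.0, -5.0]), alpha=1.0)
        assert v == pytest.approx(3.0, abs=1e-6)


class TestQTarget:
    @pytest.mark.parametrize("gamma,done,expected", [(0.9, 1.0, 0.5), (0.0, 0.0, 0.5)])
    def test_terminal_or_undiscounted_is_reward(self, gamma, done, expected):
        nets, cfg = small_networks()
        cfg.gamma = gamma
        y = q_target(
            np.array([0.5]), np.zeros((1, 3)), np.array([done]), nets, cfg
        )
        assert y[0] == pytest.approx(expected, abs=1e-9)

    def test_scalar_arithmetic(self):
        # y = r + gamma * (1 - done) * V(s'): force V(s') = 0.2 exactly by
        # zeroing the networks and biasing the target Q heads
        nets, cfg = small_networks(n_actions=2)
        cfg.gamma = 0.9
        cfg.alpha = 1e-12  # entropy negligible
        for net in (nets.policy, nets.q1_target, nets.q2_target):
            for w in net.W:
                w[:] = 0.0
            for b in net.b:
                b[:] = 0.0
        nets.q1_target.b[-1][:] = 0.2
        nets.q2_target.b[-1][:] = 0.3  # min picks 0.2
        y = q_target(np.array([0.5]), np.zeros((1, 3)), np.array([0.0]), nets, cfg)
        assert y[0] == pytest.approx(0.5 + 0.9 * 0.2, abs=1e-9)

    def test_uses_min_of_target_networks(self):
        nets, cfg = small_networks(n_actions=2)
        cfg.alpha = 1e-12
        cfg.gamma = 1.0
        for net in (nets.policy, nets.q1_target, nets.q2_target):
            for w in net.W:
                w[:] = 0.0
            for b in net.b:
                b[:] = 0.0
        nets.q1_target.b[-1][:] = 5.0
        nets.q2_target.b[-1][:] = -1.0
        y = q_target(np.array([0.0]), np.zeros((1, 3)), np.array([0.0]), nets, cfg)
        assert y[0] == pytest.approx(-1.0, abs=1e-9)


def fixed_batch(rng, nets, cfg, n=16):
    return {
        "s": rng.normal(size=(n, 3)),
        "a": rng.integers(nets.n_actions, size=n),
        "r": rng.uniform(size=n),
        "s_next": rng.normal(size=(n, 3)),
        "done": (rng.uniform(size=n) < 0.5).astype(float),
    }


class TestUpdateQ:
    def test_loss_decreases_overfitting_one_batch(self, rng):
        nets, cfg = small_networks(seed=2)
        cfg.lr = 1e-2
        batch = fixed_batch(rng, nets, cfg)
        first = update_q(nets, batch, cfg)
        for _ in range(1000):
            last = update_q(nets, batch, cfg)
        assert last[0] < first[0] * 0.1
        assert last[1] < first[1] * 0.1

    def test_target_networks_not_touched_by_q_update(self, rng):
        nets, cfg = small_networks(seed=3)
        before = [p.copy() for p in nets.q1_target.parameters()]
        update_q(nets, fixed_batch(rng, nets, cfg), cfg)
        for a, b in zip(before, nets.q1_target.parameters()):
            assert np.array_equal(a, b)


class TestUpdatePolicy:
    def test_bandit_converges_to_softmax_q_over_alpha(self, rng):
        # one state, two actions, Q fixed at [1, 0], alpha = 1:
        # optimum is softmax([1, 0]) = [0.731, 0.269]
        nets, cfg = small_networks(n_actions=2, alpha=1.0, seed=4)
        cfg.lr = 5e-3
        for net, val in ((nets.q1, 0.0), (nets.q2, 0.0)):
            for w in net.W:
                w[:] = 0.0
            for b in net.b:
                b[:] = 0.0
        nets.q1.b[-1][:] = [1.0, 0.0]
        nets.q2.b[-1][:] = [1.0, 0.0]
        batch = {"s": np.ones((4, 3))}
        for _ in range(5000):
            update_policy(nets, batch, cfg)
        p = policy_distribution(nets, np.ones(3))
        target = np.exp([1.0, 0.0]) / np.exp([1.0, 0.0]).sum()
        assert np.abs(p - target).sum() < 1e-2  # total variation x2

    def test_small_alpha_concentrates_on_argmax(self):
        nets, cfg = small_networks(n_actions=3, alpha=1e-3, seed=5)
        cfg.lr = 1e-2
        for net in (nets.q1, nets.q2):
            for w in net.W:
                w[:] = 0.0
            for b in net.b:
                b[:] = 0.0
            net.b[-1][:] = [0.0, 1.0, 0.5]
        batch = {"s": np.ones((4, 3))}
        for _ in range(5000):
            update_policy(nets, batch, cfg)
        p = policy_distribution(nets, np.ones(3))
        assert np.argmax(p) == 1
        assert p[1] > 0.95

    def test_q_networks_frozen_during_policy_step(self, rng):
        nets, cfg = small_networks(seed=6)
        before = [p.copy() for p in nets.q1.parameters()]
        update_policy(nets, {"s": rng.normal(size=(8, 3))}, cfg)
        for a, b in zip(before, nets.q1.parameters()):
            assert np.array_equal(a, b)


class TestPolyak:
    def test_tau_one_keeps_targets(self):
        nets, _ = small_networks(seed=7)
        before = [p.copy() for p in nets.q1_target.parameters()]
        nets.q1.W[0][:] += 1.0
        polyak_update(nets, tau=1.0)
        for a, b in zip(before, nets.q1_target.parameters()):
            assert np.array_equal(a, b)

    def test_tau_zero_copies_locals(self):
        nets, _ = small_networks(seed=8)
        nets.q1.W[0][:] += 1.0
        polyak_update(nets, tau=0.0)
        assert np.array_equal(nets.q1_target.W[0], nets.q1.W[0])

    def test_scalar_arithmetic(self):
        nets, _ = small_networks(seed=9)
        nets.q1_target.W[0][:] = 0.0
        nets.q1.W[0][:] = 1.0
        polyak_update(nets, tau=0.995)
        assert np.allclose(nets.q1_target.W[0], 0.005)

    def test_targets_equal_locals_at_init(self):
        nets, _ = small_networks(seed=10)
        for a, b in zip(nets.q1.parameters(), nets.q1_target.parameters()):
            assert np.array_equal(a, b)


class TestReplayBuffer:
    def test_fifo_eviction_and_batch_without_replacement(self, rng):
        buf = ReplayBuffer(4, 1, rng)
        for i in range(6):
            buf.add(Transition(np.array([float(i)]), 0, 0.0, np.array([0.0]), False))
        assert buf.size == 4
        batch = buf.sample(4)
        assert sorted(batch["s"].ravel()) == [2.0, 3.0, 4.0, 5.0]

    def test_sample_too_large(self, rng):
        buf = ReplayBuffer(4, 1, rng)
        with pytest.raises(ValueError):
            buf.sample(1)


class TestTrainLoop:
    def test_no_updates_before_cadence_or_warmup(self):
        env = BanditEnv([0.0, 1.0])
        cfg = SACConfig(seed=0, warmup_steps=100, update_every=16, hidden_sizes=(8,))
        agent, log = train(env, cfg, budget=8)
        assert agent.buffer.size == 8
        assert agent.networks.opt_q1.t == 0  # zero gradient steps
        assert len(log) == 8  # bandit episodes are single steps

    def test_bandit_training_learns_best_arm(self):
        env = BanditEnv([0.2, 1.0, 0.0])
        cfg = SACConfig(
            seed=1, alpha=0.05, lr=3e-3, warmup_steps=50, batch_size=32,
            update_every=1, hidden_sizes=(16,),
        )
        agent, _ = train(env, cfg, budget=1500)
        assert agent.act(env.reset(), greedy=True) == 1

    def test_fixed_seed_identical_logs(self):
        from copsense.environment import EnvConfig, SensorPlacementEnv
        from copsense.synthetic import make_testing_video

        video = make_testing_video()

        def run():
            env = SensorPlacementEnv([video], EnvConfig(seed=0))
            cfg = SACConfig(seed=13, warmup_steps=64, batch_size=16,
                            hidden_sizes=(32,), obs_scale=1 / 8)
            _, log = train(env, cfg, budget=600)
            return log

        assert run() == run()

    def test_checkpoint_roundtrip(self, tmp_path):
        env = BanditEnv([0.0, 1.0])
        cfg = SACConfig(seed=2, warmup_steps=10, batch_size=8,
                        update_every=1, hidden_sizes=(8,))
        agent, _ = train(env, cfg, budget=50)
        path = tmp_path / "agent.npz"
        agent.save(path)
        clone = SACAgent(BanditEnv([0.0, 1.0]), cfg)
        clone.load(path)
        obs = np.zeros(1)
        assert np.allclose(
            policy_distribution(agent.networks, obs),
            policy_distribution(clone.networks, obs),
        )
        assert clone.total_steps == agent.total_steps
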