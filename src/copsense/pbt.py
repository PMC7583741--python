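"""Population-based training over the entropy temperature.

A population of SAC-Discrete agents trains in parallel; periodically each
member is evaluated (mean of its last 10 episodic rewards) and, once it
has accumulated enough agent steps since its last ready event, passes
through exploit-and-explore: a member ranked in the bottom 20% of the
population copies the network parameters and temperature of a uniformly
drawn top-20% member and then perturbs the temperature by a factor of
0.8 or 1.2. Members outside the bottom set are left untouched, so a
temperature trajectory only moves at ready events.

Scheduling is synchronous round-robin in fixed step slices, which makes a
whole population run bit-reproducible from one seed on one machine.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .sac import SACAgent, SACConfig

__all__ = [
    "PBTConfig",
    "PBTMember",
    "eval_member",
    "ready",
    "exploit",
    "explore",
    "run_population",
]


@dataclass
class PBTConfig:
    population_size: int = 15
    exploit_fraction: float = 0.2
    perturb_factors: tuple[float, float] = (0.8, 1.2)
    ready_interval: int = 500_000  # agent steps between ready events
    alpha_range: tuple[float, float] = (1e-3, 1e-1)  # log-uniform init
    slice_steps: int = 10_000  # round-robin training slice
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")
        if not 0.0 < self.exploit_fraction <= 0.5:
            raise ValueError("exploit_fraction must be in (0, 0.5]")
        lo, hi = self.alpha_range
        if not 0 < lo <= hi:
            raise ValueError("alpha_range must satisfy 0 < lo <= hi")

    def cutoff(self) -> int:
        """Size of the top and bottom sets: ceil(fraction * N)."""
        return math.ceil(self.exploit_fraction * self.population_size)


@dataclass
class PBTMember:
    """One population slot: an agent, its temperature, and bookkeeping."""

    index: int
    agent: SACAgent
    alpha: float
    perf: float | None = None
    steps_since_ready: int = 0
    alpha_history: list[tuple[int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.set_alpha(self.alpha)

    def set_alpha(self, alpha: float) -> None:
        if alpha <= 0:
            raise ValueError("alpha must be > 0")
        self.alpha = alpha
        self.agent.config.alpha = alpha
        self.alpha_history.append((self.agent.total_steps, alpha))


def eval_member(member: PBTMember, window: int = 10) -> float:
    """Mean of the last ``window`` episodic rewards (fewer if short history)."""
    rewards = member.agent.episode_rewards()
    if not rewards:
        raise ValueError(f"member {member.index} has no completed episodes")
    return float(np.mean(rewards[-window:]))


def ready(member: PBTMember, ready_interval: int) -> bool:
    """True once the member has run ``ready_interval`` agent steps since
    its last ready event. The counter is reset by the caller after the
    exploit/explore pass."""
    return member.steps_since_ready >= ready_interval


def _ranked(population: Sequence[PBTMember]) -> list[PBTMember]:
    for m in population:
        if m.perf is None:
            raise ValueError(f"member {m.index} has not been evaluated")
    # stable sort, descending perf; ties broken by member index
    return sorted(population, key=lambda m: (-m.perf, m.index))


def exploit(
    member: PBTMember,
    population: Sequence[PBTMember],
    rng: np.random.Generator,
    exploit_fraction: float = 0.2,
) -> bool:
    """Bottom-set members copy parameters and temperature from a random
    top-set member. Returns True iff a copy happened."""
    ranked = _ranked(population)
    k = math.ceil(exploit_fraction * len(ranked))
    bottom = ranked[len(ranked) - k :]
    if member not in bottom:
        return False
    top = ranked[:k]
    source = top[int(rng.integers(len(top)))]
    if source is member:  # degenerate tiny populations
        return False
    member.agent.networks.copy_from(source.agent.networks)
    member.set_alpha(source.alpha)
    return True


def explore(
    member: PBTMember,
    rng: np.random.Generator,
    factors: tuple[float, float] = (0.8, 1.2),
) -> float:
    """Perturb the temperature by a uniformly drawn factor; returns it."""
    f = factors[int(rng.integers(len(factors)))]
    member.set_alpha(member.alpha * f)
    return f


def init_population(
    env_factory: Callable[[int], object],
    config: PBTConfig,
    sac_config: SACConfig,
) -> list[PBTMember]:
    """Create members with log-uniform temperatures and spawned seeds."""
    ss = np.random.SeedSequence(config.seed)
    init_rng = np.random.default_rng(ss.spawn(1)[0])
    lo, hi = config.alpha_range
    members = []
    for i in range(config.population_size):
        alpha = float(np.exp(init_rng.uniform(np.log(lo), np.log(hi))))
        member_seed = int(ss.generate_state(config.population_size + 1)[i + 1] % (2**31))
        cfg = SACConfig(**{**sac_config.__dict__, "alpha": alpha, "seed": member_seed})
        agent = SACAgent(env_factory(i), cfg)
        members.append(PBTMember(index=i, agent=agent, alpha=alpha))
    return members


def run_population(
    env_factory: Callable[[int], object],
    config: PBTConfig,
    sac_config: SACConfig,
    steps_per_member: int,
) -> tuple[PBTMember, list[PBTMember]]:
    """Train every member for ``steps_per_member`` agent steps.

    Members train in round-robin slices of ``config.slice_steps`` (each
    member sees its own stream of episodes, as if running in parallel).
    After each slice the member is evaluated and, if ready, passes
    through exploit (and explore, only after an actual copy — a member
    that kept its own parameters keeps its temperature).
    Returns (best member by final perf, all members).
    """
    members = init_population(env_factory, config, sac_config)
    pbt_rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    per_member = steps_per_member
    trained = [0] * len(members)
    while any(t < per_member for t in trained):
        for m in members:
            remaining = per_member - trained[m.index]
            if remaining <= 0:
                continue
            chunk = min(config.slice_steps, remaining)
            m.agent.train_steps(chunk)
            trained[m.index] += chunk
            m.steps_since_ready += chunk
            if m.agent.episode_rewards():
                m.perf = eval_member(m)
            if (
                len(members) > 1
                and ready(m, config.ready_interval)
                and all(x.perf is not None for x in members)
            ):
                copied = exploit(m, members, pbt_rng, config.exploit_fraction)
                if copied:
                    explore(m, pbt_rng, config.perturb_factors)
                    m.perf = eval_member(m)
                m.steps_since_ready = 0
    best = max(members, key=lambda m: (m.perf if m.perf is not None else -np.inf, -m.index))
    return best, members


def write_member_logs(members: Sequence[PBTMember], out_dir: str | Path) -> None:
    """One JSONL file per member: {episode, reward, alpha, steps}."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for m in members:
        path = out / f"member_{m.index:02d}.jsonl"
        with path.open("w") as fh:
            for rec in m.agent.episode_log:
                fh.write(json.dumps(rec) + "\n")
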