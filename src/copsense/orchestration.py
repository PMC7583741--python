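"""End-to-end experiment runs: config, logging, curves, final placement.

A run is fully determined by its :class:`RunConfig` (synchronous
scheduling): it builds the video source (generated testing video,
generated gait dataset, or a directory of ``.ppv`` files), trains a PBT
population of SAC-Discrete agents, and writes to the run directory

* ``config.yaml`` — the resolved configuration echo,
* ``members/member_XX.jsonl`` — per-episode {episode, reward, alpha, steps},
* ``curves.png`` / ``alpha.png`` — moving-average reward curves and
  temperature traces,
* ``placement.json`` — the best member's greedy-rollout placement,
* ``summary.json`` — final performance numbers.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cop_reward import Placement, write_placement
from .environment import EnvConfig, SensorPlacementEnv
from .pbt import PBTConfig, PBTMember, run_population, write_member_logs
from .pressure_video import read_video
from .sac import SACConfig
from .synthetic import TestingVideoSpec, make_gait_dataset, make_testing_video

__all__ = ["RunConfig", "run_experiment", "moving_average"]


@dataclass
class RunConfig:
    env: EnvConfig = field(default_factory=EnvConfig)
    sac: SACConfig = field(default_factory=SACConfig)
    pbt: PBTConfig = field(default_factory=PBTConfig)
    budget: int = 10_000_000  # agent steps per population member
    out_dir: str = "runs/run"
    seed: int = 0
    video_source: str = "testing"  # "testing" | "gait:<n>" | a directory path
    moving_average_window: int = 1000
    final_window: int = 1000  # episodes averaged for the headline number

    def resolved(self) -> "RunConfig":
        """Propagate the global seed and derived scalings."""
        self.sac.seed = self.seed
        self.pbt.seed = self.seed
        self.env.seed = self.seed
        if self.sac.obs_scale == 1.0 and self.env.n_sensors > 1:
            self.sac.obs_scale = 1.0 / self.env.n_sensors
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["env"]["reward_params"] = {
            "exponent": self.env.reward_params.exponent,
            "maxdistance": self.env.reward_params.maxdistance,
        }
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for section in ("env", "sac", "pbt"):
            if section in raw:
                sub = getattr(cfg, section)
                for k, v in raw[section].items():
                    if not hasattr(sub, k):
                        raise ValueError(f"unknown key {section}.{k}")
                    setattr(sub, k, tuple(v) if isinstance(v, list) else v)
        for k, v in raw.items():
            if k in ("env", "sac", "pbt"):
                continue
            if not hasattr(cfg, k):
                raise ValueError(f"unknown key {k}")
            setattr(cfg, k, v)
        return cfg


def diagnostic_run_config(
    seed: int, out_dir: str, budget: int = 70_000, population_size: int = 3
) -> RunConfig:
    """Desk-scale testing-video experiment: a small population trained on
    the generated diagnostic video, ~2x10^5 agent steps in total (the
    full-scale counterpart uses 15 members and 10 M steps each)."""
    cfg = RunConfig(
        budget=budget,
        out_dir=out_dir,
        seed=seed,
        video_source="testing",
        moving_average_window=1000,
    )
    cfg.pbt.population_size = population_size
    cfg.pbt.ready_interval = 20_000
    cfg.pbt.slice_steps = 4_000
    return cfg


def moving_average(values, window: int) -> np.ndarray:
    """Trailing moving average; early entries average the available history,
    so a constant series maps to itself."""
    x = np.asarray(values, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    c = np.concatenate([[0.0], np.cumsum(x)])
    n = len(x)
    lo = np.maximum(np.arange(n) - window + 1, 0)
    return (c[np.arange(n) + 1] - c[lo]) / (np.arange(n) + 1 - lo)


def _load_videos(config: RunConfig):
    src = config.video_source
    if src == "testing":
        return [make_testing_video(TestingVideoSpec(grid=config.env.grid))]
    if src.startswith("gait:"):
        n = int(src.split(":", 1)[1])
        return make_gait_dataset(n, seed=config.seed, grid=config.env.grid)
    path = Path(src)
    videos = [read_video(p) for p in sorted(path.glob("*.ppv"))]
    if not videos:
        raise ValueError(f"no .ppv videos in {path}")
    return videos


def _plot_curves(members: list[PBTMember], window: int, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for m in members:
        rewards = m.agent.episode_rewards()
        if rewards:
            ax.plot(moving_average(rewards, window), lw=0.8, label=f"member {m.index}")
    ax.set_xlabel("episode")
    ax.set_ylabel(f"episodic reward (moving average, window {window})")
    if len(members) <= 5:
        ax.legend(fontsize=7)
    fig.savefig(out_dir / "curves.png", dpi=150, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(7, 4))
    for m in members:
        steps, alphas = zip(*m.alpha_history)
        ax.step(steps, alphas, where="post", lw=0.8)
    ax.set_yscale("log")
    ax.set_xlabel("agent steps")
    ax.set_ylabel("temperature alpha")
    fig.savefig(out_dir / "alpha.png", dpi=150, bbox_inches="tight")
    plt.close(fig)


def run_experiment(config: RunConfig, plots: bool = True) -> dict:
    """Execute a full (possibly scaled-down) training run.

    Returns the summary dict that is also written to ``summary.json``.
    """
    config = config.resolved()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))

    if config.budget <= 0:
        (out_dir / "members").mkdir(exist_ok=True)
        summary = {"episodes": 0, "members": []}
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=1))
        return summary

    videos = _load_videos(config)

    def env_factory(i: int) -> SensorPlacementEnv:
        return SensorPlacementEnv(videos, config.env)

    best, members = run_population(
        env_factory, config.pbt, config.sac, config.budget
    )
    write_member_logs(members, out_dir / "members")

    actions, greedy_reward = best.agent.greedy_rollout()
    h, w = config.env.grid
    cells = [divmod(a, w) for a in actions]
    placement = Placement.from_cells(cells, (h, w), n_sensors=config.env.n_sensors)
    write_placement(placement, out_dir / "placement.json")

    rewards = best.agent.episode_rewards()
    final = rewards[-config.final_window :]
    summary = {
        "episodes": sum(len(m.agent.episode_rewards()) for m in members),
        "best_member": best.index,
        "best_perf": best.perf,
        "best_alpha": best.alpha,
        "greedy_reward": greedy_reward,
        "greedy_actions": [int(a) for a in actions],
        "final_mean_reward": float(np.mean(final)),
        "final_window_used": len(final),
        "members": [
            {
                "index": m.index,
                "perf": m.perf,
                "alpha": m.alpha,
                "episodes": len(m.agent.episode_rewards()),
            }
            for m in members
        ],
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1))
    if plots:
        _plot_curves(members, config.moving_average_window, out_dir)
        env = env_factory(0)
        env.reset()
        env._counts = placement.counts.copy()
        env.render(str(out_dir / "placement.png"))
    best.agent.save(out_dir / "best_agent.npz")
    return summary
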