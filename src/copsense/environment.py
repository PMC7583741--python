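"""The sensor-placement decision process.

An episode starts from an empty board (default 20 x 7) with a budget of
sensors (default 8) and a pressure video drawn uniformly from the
configured dataset. Each step places one sensor on a cell (repeats
allowed; duplicates are equivalent under the coverage mask) and the
episode ends when the budget is spent, so every episode is exactly
``n_sensors`` steps long. Actions are flat row-major cell indices,
``action = y * W + x``.

Two reward modes:

* ``terminal`` — zero reward on non-terminal steps, the episode reward
  of the final placement at termination (the raw delayed-reward task);
* ``redistributed`` — the difference of accumulative rewards of the
  placement prefix before and after the step, which sums to the same
  terminal reward exactly but gives per-step credit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cop_reward import Placement, RewardParams, episode_reward
from .pressure_video import PressureVideo

__all__ = ["BoardState", "EnvConfig", "SensorPlacementEnv"]


@dataclass(frozen=True)
class BoardState:
    """Observation: the sensor-count grid plus remaining budget."""

    counts: np.ndarray
    sensors_remaining: int

    def observation(self) -> np.ndarray:
        """The count grid as a float array (what the networks see)."""
        return self.counts.astype(float)


@dataclass
class EnvConfig:
    grid: tuple[int, int] = (20, 7)
    n_sensors: int = 8
    reward_mode: str = "redistributed"  # or "terminal"
    reward_params: RewardParams = field(default_factory=RewardParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sensors < 1:
            raise ValueError("n_sensors must be >= 1")
        if self.reward_mode not in ("terminal", "redistributed"):
            raise ValueError(f"unknown reward_mode {self.reward_mode!r}")


class SensorPlacementEnv:
    """Discrete-action environment over a dataset of pressure videos.

    Implements the standard reset/step/seed contract: ``reset`` returns
    the initial observation, ``step`` returns ``(obs, reward, done)``.
    """

    def __init__(self, videos: Sequence[PressureVideo], config: EnvConfig | None = None):
        if len(videos) == 0:
            raise ValueError("empty video dataset")
        self.config = config or EnvConfig()
        h, w = self.config.grid
        for i, v in enumerate(videos):
            if v.shape != (h, w):
                raise ValueError(
                    f"video {i} has shape {v.shape}, environment grid is {(h, w)}"
                )
        self.videos = list(videos)
        self._rng = np.random.default_rng(self.config.seed)
        self._counts: np.ndarray | None = None
        self._remaining = 0
        self._video: PressureVideo | None = None
        self._video_index: int | None = None
        self._accumulative = 0.0
        self.episode_video_log: list[int] = []

    # -- RL protocol -------------------------------------------------------

    @property
    def n_actions(self) -> int:
        h, w = self.config.grid
        return h * w

    @property
    def observation_shape(self) -> tuple[int, int]:
        return self.config.grid

    def seed(self, seed: int) -> None:
        self._rng = np.random.default_rng(seed)

    def reset(self) -> np.ndarray:
        self._video_index = int(self._rng.integers(len(self.videos)))
        self._video = self.videos[self._video_index]
        self.episode_video_log.append(self._video_index)
        h, w = self.config.grid
        self._counts = np.zeros((h, w), dtype=int)
        self._remaining = self.config.n_sensors
        self._accumulative = 0.0  # empty placement scores 0 by convention
        return self.state.observation()

    def step(self, action: int) -> tuple[np.ndarray, float, bool]:
        if self._counts is None:
            raise RuntimeError("call reset() before step()")
        if self._remaining <= 0:
            raise RuntimeError("episode is done; call reset()")
        action = int(action)
        if not 0 <= action < self.n_actions:
            raise ValueError(f"action {action} out of range [0, {self.n_actions})")
        y, x = self.unflatten(action)
        self._counts[y, x] += 1
        self._remaining -= 1
        done = self._remaining == 0
        if self.config.reward_mode == "terminal":
            reward = self._terminal_reward() if done else 0.0
        else:
            acc = self._prefix_reward()
            reward = acc - self._accumulative
            self._accumulative = acc
        return self.state.observation(), float(reward), done

    # -- helpers -----------------------------------------------------------

    @property
    def state(self) -> BoardState:
        return BoardState(self._counts.copy(), self._remaining)

    @property
    def episode_video(self) -> PressureVideo:
        if self._video is None:
            raise RuntimeError("no active episode")
        return self._video

    def unflatten(self, action: int) -> tuple[int, int]:
        w = self.config.grid[1]
        return divmod(action, w)

    def flatten(self, y: int, x: int) -> int:
        return y * self.config.grid[1] + x

    def _placement(self) -> Placement:
        return Placement(self._counts.copy(), n_sensors=self.config.n_sensors)

    def _prefix_reward(self) -> float:
        return episode_reward(
            self._video, self._placement(), self.config.reward_params
        )

    def _terminal_reward(self) -> float:
        return self._prefix_reward()

    def render(self, path: str) -> None:
        """Write a PNG of sensor counts over the accumulated pressure image."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(3, 6))
        background = sum(v.frames.sum(axis=0) for v in self.videos)
        ax.imshow(background, cmap="inferno", origin="upper")
        if self._counts is not None:
            ys, xs = np.nonzero(self._counts)
            for y, x in zip(ys, xs):
                ax.plot(x, y, "o", color="cyan", markersize=8)
                ax.annotate(
                    str(self._counts[y, x]), (x, y), color="white",
                    ha="center", va="center", fontsize=6,
                )
        ax.set_xticks([])
        ax.set_yticks([])
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
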