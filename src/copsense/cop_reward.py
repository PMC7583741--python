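"""Center-of-pressure trajectories and the placement reward.

The center of pressure (COP) of a pressure frame is the pressure-weighted
centroid of the grid, in continuous 0-based cell units:

    COP_n = ( sum(p * x) / sum(p), sum(p * y) / sum(p) )

A sensor placement is judged by how well the COP trajectory recovered
from only the covered cells matches the full-field trajectory. Per frame
the Euclidean distance d_n between the two COPs is normalized by
``maxdistance = sqrt(W^2 + H^2)`` and the episode reward is

    reward = (1 - mean_n d_n / maxdistance) ** 0.4

which lies in [0, 1]; the exponent 0.4 sharpens resolution near small
distances. Frames whose full-field COP is undefined (zero total
pressure) are excluded from the mean; frames where only the masked COP
is undefined (the placement captures no pressure) incur the maximal
distance. The delayed terminal reward is redistributed over the eight
placement steps by differencing accumulative rewards of placement
prefixes, which telescopes exactly to the terminal reward.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .pressure_video import PressureVideo

__all__ = [
    "COPTrajectory",
    "Placement",
    "RewardParams",
    "cop_trajectory",
    "apply_mask",
    "episode_reward",
    "redistribute",
    "read_placement",
    "write_placement",
]


@dataclass(frozen=True)
class COPTrajectory:
    """Per-frame COP points; ``defined[n]`` is False for empty frames.

    ``x`` is the mediolateral (column) coordinate, ``y`` the
    anteroposterior (row) coordinate, both 0-based cell units.
    """

    x: np.ndarray
    y: np.ndarray
    defined: np.ndarray

    def __len__(self) -> int:
        return len(self.defined)

    def point(self, n: int) -> tuple[float, float, bool]:
        return float(self.x[n]), float(self.y[n]), bool(self.defined[n])


@dataclass(frozen=True)
class Placement:
    """A multiset of sensor positions as an H x W count grid."""

    counts: np.ndarray
    n_sensors: int = 8

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2D grid")
        if np.any(counts < 0):
            raise ValueError("sensor counts must be non-negative")
        if counts.sum() > self.n_sensors:
            raise ValueError(
                f"placement uses {counts.sum()} sensors but only "
                f"{self.n_sensors} are available"
            )
        object.__setattr__(self, "counts", counts)

    @classmethod
    def empty(cls, shape: tuple[int, int], n_sensors: int = 8) -> "Placement":
        return cls(np.zeros(shape, dtype=int), n_sensors=n_sensors)

    @classmethod
    def from_cells(
        cls,
        cells: Sequence[tuple[int, int]],
        shape: tuple[int, int],
        n_sensors: int | None = None,
    ) -> "Placement":
        """Build a placement from (y, x) cells; duplicates accumulate."""
        counts = np.zeros(shape, dtype=int)
        for y, x in cells:
            counts[y, x] += 1
        return cls(counts, n_sensors=len(cells) if n_sensors is None else n_sensors)

    def cells(self) -> list[tuple[int, int]]:
        """Occupied (y, x) cells with multiplicity, row-major order."""
        out = []
        for (y, x), c in np.ndenumerate(self.counts):
            out.extend([(int(y), int(x))] * int(c))
        return out

    def mask(self) -> np.ndarray:
        """Boolean coverage mask; duplicate sensors are equivalent."""
        return self.counts > 0


@dataclass(frozen=True)
class RewardParams:
    """Reward shape parameters.

    ``exponent`` sharpens the score near zero distance; ``maxdistance``
    is the normalization constant, by default the grid diagonal
    sqrt(W^2 + H^2) in cell units (None = derive from the video).
    """

    exponent: float = 0.4
    maxdistance: float | None = None

    def __post_init__(self) -> None:
        if self.exponent <= 0:
            raise ValueError("exponent must be > 0")
        if self.maxdistance is not None and self.maxdistance <= 0:
            raise ValueError("maxdistance must be > 0")

    def resolve_maxdistance(self, shape: tuple[int, int]) -> float:
        if self.maxdistance is not None:
            return self.maxdistance
        h, w = shape
        return float(np.hypot(w, h))


def cop_trajectory(video: PressureVideo) -> COPTrajectory:
    """Pressure-weighted centroid per frame; empty frames are undefined.

    The result is cached on the (immutable) video, so repeated scoring
    of placements against the same video pays for the full-field
    trajectory only once.
    """
    cached = getattr(video, "_cop_cache", None)
    if cached is not None:
        return cached
    frames = video.frames
    totals = frames.sum(axis=(1, 2))
    defined = totals > 0
    xs = np.arange(video.width, dtype=float)
    ys = np.arange(video.height, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        x = frames.sum(axis=1) @ xs / totals
        y = frames.sum(axis=2) @ ys / totals
    x = np.where(defined, x, np.nan)
    y = np.where(defined, y, np.nan)
    traj = COPTrajectory(x=x, y=y, defined=defined)
    object.__setattr__(video, "_cop_cache", traj)
    return traj


def apply_mask(video: PressureVideo, placement: Placement) -> PressureVideo:
    """Zero out pressure outside the covered cells."""
    if placement.counts.shape != video.shape:
        raise ValueError(
            f"placement grid {placement.counts.shape} does not match "
            f"video shape {video.shape}"
        )
    # plain PressureVideo: masking may empty frames of a stance clip
    return PressureVideo(
        video.frames * placement.mask(),
        frame_rate=video.frame_rate,
        cell_area=video.cell_area,
    )


def _frame_distances(
    video: PressureVideo, placement: Placement, maxdistance: float
) -> np.ndarray:
    """Per-frame COP distances over frames with a defined full-field COP."""
    full = cop_trajectory(video)
    keep = full.defined
    if not keep.any():
        raise ValueError("no defined COP frames: every frame is empty")
    # masked COP straight from the masked pressure sums (skips rebuilding
    # a video object per scoring call)
    frames = video.frames[keep] * placement.mask()
    totals = frames.sum(axis=(1, 2))
    m_def = totals > 0
    xs = np.arange(video.width, dtype=float)
    ys = np.arange(video.height, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = frames.sum(axis=1) @ xs / totals
        my = frames.sum(axis=2) @ ys / totals
    d = np.hypot(full.x[keep] - mx, full.y[keep] - my)
    # masked COP undefined on a frame the full COP exists -> maximal penalty
    return np.where(m_def, d, maxdistance)


def episode_reward(
    video: PressureVideo,
    placement: Placement,
    params: RewardParams = RewardParams(),
) -> float:
    """Score a placement against a video; result in [0, 1].

    1.0 iff the masked COP coincides with the full-field COP on every
    frame where the latter is defined.
    """
    maxd = params.resolve_maxdistance(video.shape)
    d = _frame_distances(video, placement, maxd)
    base = 1.0 - float(d.mean()) / maxd
    return float(max(base, 0.0) ** params.exponent)


def redistribute(
    video: PressureVideo,
    action_sequence: Sequence[tuple[int, int]],
    params: RewardParams = RewardParams(),
    n_sensors: int | None = None,
) -> list[float]:
    """Per-step rewards for a placement sequence of (y, x) cells.

    The accumulative reward A_t is the episode reward of the placement
    prefix after t actions (A_0 = 0 for the empty placement); the step
    reward is r_t = A_t - A_{t-1}. The sum telescopes to the terminal
    episode reward exactly. Placing on an already covered cell yields 0;
    negative step rewards are possible.
    """
    n_sensors = len(action_sequence) if n_sensors is None else n_sensors
    counts = np.zeros(video.shape, dtype=int)
    rewards: list[float] = []
    prev = 0.0
    for y, x in action_sequence:
        counts[y, x] += 1
        acc = episode_reward(
            video, Placement(counts, n_sensors=n_sensors), params
        )
        rewards.append(acc - prev)
        prev = acc
    return rewards


# ---------------------------------------------------------------------------
# Placement JSON I/O: {"grid": [H, W], "sensors": [[y, x], ...]}
# ---------------------------------------------------------------------------


def write_placement(placement: Placement, path: str | Path) -> None:
    h, w = placement.counts.shape
    data = {"grid": [h, w], "sensors": placement.cells()}
    Path(path).write_text(json.dumps(data, indent=1) + "\n")


def read_placement(path: str | Path, n_sensors: int | None = None) -> Placement:
    data = json.loads(Path(path).read_text())
    if set(data) - {"grid", "sensors"}:
        raise ValueError(f"unexpected keys in placement file: {sorted(data)}")
    h, w = (int(v) for v in data["grid"])
    sensors = [(int(y), int(x)) for y, x in data["sensors"]]
    for y, x in sensors:
        if not (0 <= y < h and 0 <= x < w):
            raise ValueError(f"sensor ({y}, {x}) outside {h}x{w} grid")
    return Placement.from_cells(sensors, (h, w), n_sensors=n_sensors)
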