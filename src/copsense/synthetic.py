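"""Synthetic pressure videos and exhaustive placement oracles.

Two generators:

* :func:`make_testing_video` — a deliberately simple diagnostic clip:
  empty first and last frames, and in between a fixed set of at most
  ``n_sensors`` support cells whose magnitudes ramp up and then down.
  Because the support fits under the sensor budget, a placement covering
  every support cell reproduces the COP trajectory exactly and the
  maximum attainable episode reward is exactly 1.
* :func:`make_gait_video` — a parametric stance-phase clip: a 2D
  Gaussian pressure blob travelling heel to toe with the double-hump
  (loading / push-off) total-force profile typical of stance, plus
  seeded multiplicative noise.

Also here: a brute-force search over sensor subsets (duplicates never
change the coverage mask, so subset enumeration finds the true optimum
of the multiset placement space) and the mean-reward evaluation protocol
used to compare placements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np

from .cop_reward import Placement, RewardParams, episode_reward
from .pressure_video import PressureVideo, StanceVideo

__all__ = [
    "TestingVideoSpec",
    "GaitVideoSpec",
    "make_testing_video",
    "make_gait_video",
    "make_gait_dataset",
    "brute_force_optimal",
    "evaluate_placement",
    "naive_two_column_placement",
]

_DEFAULT_SUPPORT = (
    (2, 3), (4, 3), (6, 3), (8, 3), (11, 3), (13, 3), (15, 3), (17, 3),
)  # midline cells along the anteroposterior axis


@dataclass(frozen=True)
class TestingVideoSpec:
    __test__ = False  # not a pytest class despite the name

    grid: tuple[int, int] = (20, 7)
    support_cells: tuple[tuple[int, int], ...] = _DEFAULT_SUPPORT
    n_frames: int = 12  # including the empty first and last frames
    peak_pressure: float = 100.0  # kPa at the ramp apex
    frame_rate: float = 100.0

    def __post_init__(self) -> None:
        if self.n_frames < 3:
            raise ValueError("need at least 3 frames (empty, active, empty)")
        if len(set(self.support_cells)) != len(self.support_cells):
            raise ValueError("support cells must be distinct")
        h, w = self.grid
        for y, x in self.support_cells:
            if not (0 <= y < h and 0 <= x < w):
                raise ValueError(f"support cell ({y}, {x}) outside {h}x{w} grid")


@dataclass(frozen=True)
class GaitVideoSpec:
    grid: tuple[int, int] = (20, 7)
    n_frames: int = 30
    heel_center: tuple[float, float] = (3.0, 3.2)  # (y, x), y = posterior
    toe_center: tuple[float, float] = (16.5, 2.8)  # forefoot/toe region
    blob_sigma: tuple[float, float] = (1.6, 1.1)  # heel blob (sigma_y, sigma_x)
    hump_amplitudes: tuple[float, float] = (1.0, 1.0)  # loading, push-off
    peak_force: float = 800.0  # total force at a hump apex (kPa * cells)
    noise_scale: float = 0.05  # multiplicative pressure noise
    frame_rate: float = 100.0
    seed: int = 0


def make_testing_video(spec: TestingVideoSpec = TestingVideoSpec()) -> PressureVideo:
    """Ramp-up/ramp-down video on a small fixed support.

    A single pressure point visits the support cells in order across
    the active frames; magnitudes follow a triangular
    increase-then-decrease ramp. The full-field COP therefore steps
    through the support cells one by one. A frame whose active cell is
    covered is reproduced exactly by the masked video (zero COP
    distance); a frame whose active cell is missed leaves the masked
    video empty there and incurs the maximal distance. The episode
    reward consequently depends only on which support cells the
    placement covers — each cell contributes its own frames — and the
    maximum, exactly 1, is attained precisely by placements covering
    the whole support."""
    h, w = spec.grid
    n_support = len(spec.support_cells)
    frames = np.zeros((spec.n_frames, h, w))
    n_active = spec.n_frames - 2
    if n_active < n_support:
        raise ValueError("need at least one active frame per support cell")
    # triangular magnitude ramp over the active frames, strictly positive
    t = np.arange(1, n_active + 1) / (n_active + 1)
    ramp = 1.0 - np.abs(2.0 * t - 1.0)
    ramp = ramp / ramp.max() * spec.peak_pressure
    active_cell = (np.arange(n_active) * n_support) // n_active
    for j, mag in enumerate(ramp):
        ys, xs = spec.support_cells[active_cell[j]]
        frames[j + 1, ys, xs] = mag
    return PressureVideo(frames, frame_rate=spec.frame_rate)


def _gaussian_blob(
    shape: tuple[int, int], center: tuple[float, float], sigma: tuple[float, float]
) -> np.ndarray:
    """Unit-mass 2D Gaussian footprint, truncated below 1e-4 of the peak."""
    h, w = shape
    cy, cx = center
    sy, sx = sigma
    ys = np.arange(h)[:, None]
    xs = np.arange(w)[None, :]
    blob = np.exp(-(((ys - cy) / sy) ** 2 + ((xs - cx) / sx) ** 2) / 2.0)
    blob[blob < 1e-4] = 0.0
    return blob / blob.sum()


def make_gait_video(spec: GaitVideoSpec = GaitVideoSpec()) -> StanceVideo:
    """Running-stance clip: heel and forefoot pressure regions cross-fading
    under the double-hump total-force profile.

    The first force hump is heel loading, the second forefoot push-off;
    as weight transfers, the COP sweeps from the heel to the forefoot
    along the long axis. Each region is a concentrated Gaussian
    footprint that drifts slightly anteriorly over the stance, plus
    seeded multiplicative noise.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.linspace(0.0, 1.0, spec.n_frames)
    # stance total-force profile: loading peak ~30%, push-off peak ~72%
    a1, a2 = spec.hump_amplitudes
    profile = a1 * np.exp(-(((t - 0.30) / 0.13) ** 2)) + a2 * np.exp(
        -(((t - 0.72) / 0.13) ** 2)
    )
    profile = profile / profile.max() * spec.peak_force
    # heel -> forefoot weight transfer (smoothstep in stance time)
    s = np.clip((t - 0.15) / 0.6, 0.0, 1.0)
    w_fore = s * s * (3.0 - 2.0 * s)
    w_heel = 1.0 - w_fore
    hy, hx = spec.heel_center
    fy, fx = spec.toe_center
    sy, sx = spec.blob_sigma
    fore_sigma = (1.3 * sy, 1.5 * sx)  # push-off spreads across metatarsals
    frames = np.zeros((spec.n_frames, *spec.grid))
    for n in range(spec.n_frames):
        heel = _gaussian_blob(spec.grid, (hy + 1.0 * t[n], hx), (sy, sx))
        fore = _gaussian_blob(spec.grid, (fy - 1.5 * (1 - t[n]), fx), fore_sigma)
        frames[n] = profile[n] * (w_heel[n] * heel + w_fore[n] * fore)
    if spec.noise_scale > 0:
        frames *= 1.0 + spec.noise_scale * rng.standard_normal(frames.shape)
        np.clip(frames, 0.0, None, out=frames)
    # trim empty lead/tail frames so the clip satisfies stance invariants
    totals = frames.sum(axis=(1, 2))
    active = np.flatnonzero(totals > 0)
    if active.size == 0:
        raise ValueError("generated video is empty; increase peak_force")
    frames = frames[active[0] : active[-1] + 1]
    if np.any(frames.sum(axis=(1, 2)) <= 0):
        raise ValueError("interior empty frame; reduce noise_scale")
    return StanceVideo(frames, frame_rate=spec.frame_rate)


def make_gait_dataset(
    n_videos: int,
    seed: int = 0,
    grid: tuple[int, int] = (20, 7),
) -> list[StanceVideo]:
    """Seeded collection of gait videos with jittered anatomy and timing."""
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    videos = []
    for i in range(n_videos):
        h, w = grid
        spec = GaitVideoSpec(
            grid=grid,
            n_frames=int(rng.integers(24, 36)),
            heel_center=(
                float(rng.uniform(0.12, 0.20) * h),
                float(rng.uniform(0.40, 0.52) * w),
            ),
            toe_center=(
                float(rng.uniform(0.78, 0.88) * h),
                float(rng.uniform(0.35, 0.48) * w),
            ),
            blob_sigma=(
                float(rng.uniform(1.3, 1.9) * h / 20),
                float(rng.uniform(0.9, 1.3) * w / 7),
            ),
            hump_amplitudes=(float(rng.uniform(0.8, 1.2)), float(rng.uniform(0.8, 1.2))),
            noise_scale=0.05,
            seed=int(rng.integers(2**31)),
        )
        videos.append(make_gait_video(spec))
    return videos


def brute_force_optimal(
    video: PressureVideo,
    n_sensors: int,
    params: RewardParams = RewardParams(),
    cap: int = 1_000_000,
) -> tuple[list[Placement], float]:
    """Exhaustively score every ``n_sensors``-subset of cells.

    Returns all tied optimal placements (lexicographic cell order) and
    the optimal reward. Feasible only on tiny instances; raises when the
    subset count C(H*W, n_sensors) exceeds ``cap``.
    """
    h, w = video.shape
    n_cells = h * w
    n_subsets = comb(n_cells, n_sensors)
    if n_subsets > cap:
        raise ValueError(
            f"C({n_cells}, {n_sensors}) = {n_subsets} subsets exceeds the "
            f"cap of {cap}; use a smaller grid or fewer sensors"
        )
    best_val = -np.inf
    best: list[tuple[tuple[int, int], ...]] = []
    all_cells = [(y, x) for y in range(h) for x in range(w)]
    for subset in combinations(all_cells, n_sensors):
        placement = Placement.from_cells(subset, (h, w), n_sensors=n_sensors)
        val = episode_reward(video, placement, params)
        if val > best_val + 1e-12:
            best_val = val
            best = [subset]
        elif abs(val - best_val) <= 1e-12:
            best.append(subset)
    placements = [
        Placement.from_cells(s, (h, w), n_sensors=n_sensors) for s in sorted(best)
    ]
    return placements, float(best_val)


def evaluate_placement(
    placement: Placement,
    videos: Sequence[PressureVideo],
    params: RewardParams = RewardParams(),
    episodes: int | None = None,
    seed: int = 0,
) -> float:
    """Mean episode reward of a fixed placement over a video set.

    With ``episodes`` given, that many videos are drawn uniformly with
    replacement (seeded) — the "average of N episodic rewards" protocol
    for comparing fixed layouts.
    """
    if len(videos) == 0:
        raise ValueError("empty video set")
    if episodes is not None:
        rng = np.random.default_rng(seed)
        idx = rng.integers(len(videos), size=episodes)
        chosen = [videos[int(i)] for i in idx]
    else:
        chosen = list(videos)
    return float(np.mean([episode_reward(v, placement, params) for v in chosen]))


def naive_two_column_placement(
    grid: tuple[int, int] = (20, 7), n_sensors: int = 8
) -> Placement:
    """A hand-designed baseline: sensors evenly spaced down two columns
    (medial and lateral), the kind of layout one would sketch without
    looking at the data."""
    h, w = grid
    per_col = n_sensors // 2
    rows = np.linspace(1, h - 2, per_col).round().astype(int)
    cols = (w // 4, 3 * w // 4)
    cells = [(int(y), int(c)) for c in cols for y in rows]
    # odd sensor counts: drop from the tail to fit the budget
    return Placement.from_cells(cells[:n_sensors], grid, n_sensors=n_sensors)
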