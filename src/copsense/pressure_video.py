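"""Plantar pressure videos and their preprocessing.

A plantar pressure video is a time sequence of 2D pressure grids (kPa)
recorded under the sole of the foot, e.g. by an in-shoe resistive sensor
array at 100 Hz. Raw recordings cover whole gait cycles; the preprocessing
pipeline here turns a raw recording into a set of fixed-resolution
stance-phase clips:

1. split at zero-pressure frames into stance-phase segments (the swing
   phase produces no pressure),
2. thin the segments by partitioning them into contiguous temporal groups
   and drawing one representative per group,
3. crop the all-zero border rows/columns,
4. downsample to a common grid (default 20 rows x 7 columns) with
   force-conserving area-weighted rebinning (pressure = force / area).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "PressureVideo",
    "StanceVideo",
    "read_video",
    "write_video",
    "split_stance_phases",
    "select_representatives",
    "crop_white_border",
    "downsample",
]


@dataclass(frozen=True)
class PressureVideo:
    """A sequence of H x W non-negative pressure grids.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, H, W)
        Pressure values in kPa. All non-negative.
    frame_rate : float
        Frames per second, > 0.
    cell_area : float
        Area of one grid cell in arbitrary but consistent units. Only
        ratios of areas matter (for force-conserving rebinning).
    """

    frames: np.ndarray
    frame_rate: float = 100.0
    cell_area: float = 1.0

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        if frames.ndim != 3:
            raise ValueError(
                f"frames must be a (n_frames, H, W) array, got shape {frames.shape}"
            )
        if frames.shape[0] == 0:
            raise ValueError("no frames")
        if np.any(frames < 0):
            bad = int(np.argwhere(frames < 0)[0, 0])
            raise ValueError(f"negative pressure in frame {bad}")
        if not np.isfinite(frames).all():
            raise ValueError("non-finite pressure value")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.cell_area <= 0:
            raise ValueError("cell_area must be > 0")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        """Cell count along the long (anteroposterior) axis."""
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        """Cell count along the mediolateral axis."""
        return self.frames.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def frame_totals(self) -> np.ndarray:
        """Total pressure per frame, shape (n_frames,)."""
        return self.frames.sum(axis=(1, 2))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PressureVideo):
            return NotImplemented
        return (
            self.frames.shape == other.frames.shape
            and np.array_equal(self.frames, other.frames)
            and self.frame_rate == other.frame_rate
            and self.cell_area == other.cell_area
        )


@dataclass(frozen=True, eq=False)
class StanceVideo(PressureVideo):
    """A stance-phase clip: every frame carries pressure somewhere.

    ``segment_index`` records which stance segment of the source
    recording the clip came from (temporal order).
    """

    segment_index: int = 0

    def __post_init__(self) -> None:
        super().__post_init__()
        totals = self.frames.sum(axis=(1, 2))
        if np.any(totals <= 0):
            bad = int(np.argmin(totals > 0))
            raise ValueError(f"stance video has an all-zero frame at index {bad}")


# ---------------------------------------------------------------------------
# File I/O: plain-text ".ppv" format and CSV frame directories.
# ---------------------------------------------------------------------------

_PPV_MAGIC = "ppv"


def write_video(video: PressureVideo, path: str | Path) -> None:
    """Write a video as plain text (``.ppv``).

    Header line ``ppv <H> <W> <frame_rate>`` followed by one block of H
    whitespace-separated rows per frame, blank line between frames.
    Values use ``repr`` precision so a round trip is bitwise exact.
    """
    path = Path(path)
    h, w = video.shape
    lines = [f"{_PPV_MAGIC} {h} {w} {video.frame_rate!r}"]
    for frame in video.frames:
        lines.append("")
        for row in frame:
            lines.append(" ".join(repr(float(v)) for v in row))
    path.write_text("\n".join(lines) + "\n")


def read_video(path: str | Path) -> PressureVideo:
    """Read a ``.ppv`` file or a directory of one-frame-per-file CSVs."""
    path = Path(path)
    if path.is_dir():
        return _read_csv_dir(path)
    text = path.read_text()
    lines = text.splitlines()
    if not lines or not lines[0].strip():
        raise ValueError(f"{path}: no frames")
    header = lines[0].split()
    if len(header) != 4 or header[0] != _PPV_MAGIC:
        raise ValueError(f"{path}: bad header {lines[0]!r}")
    h, w = int(header[1]), int(header[2])
    frame_rate = float(header[3])
    frames: list[list[list[float]]] = []
    current: list[list[float]] = []
    for line in lines[1:]:
        if not line.strip():
            if current:
                frames.append(current)
                current = []
            continue
        current.append([float(v) for v in line.split()])
    if current:
        frames.append(current)
    if not frames:
        raise ValueError(f"{path}: no frames")
    for i, frame in enumerate(frames):
        if len(frame) != h or any(len(row) != w for row in frame):
            raise ValueError(f"{path}: frame {i} is not {h}x{w} (ragged rows?)")
        if any(v < 0 for row in frame for v in row):
            raise ValueError(f"{path}: negative pressure in frame {i}")
    return PressureVideo(np.array(frames, dtype=float), frame_rate=frame_rate)


def _read_csv_dir(path: Path) -> PressureVideo:
    files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".csv")
    if not files:
        raise ValueError(f"{path}: no frames")
    frames = []
    for i, f in enumerate(files):
        with f.open(newline="") as fh:
            rows = [[float(v) for v in row] for row in csv.reader(fh) if row]
        if not rows:
            raise ValueError(f"{path}: frame {i} ({f.name}) is empty")
        widths = {len(r) for r in rows}
        if len(widths) != 1:
            raise ValueError(f"{path}: frame {i} ({f.name}) has ragged rows")
        if any(v < 0 for r in rows for v in r):
            raise ValueError(f"{path}: negative pressure in frame {i} ({f.name})")
        frames.append(rows)
    shapes = {(len(f), len(f[0])) for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"{path}: frames disagree on shape: {sorted(shapes)}")
    return PressureVideo(np.array(frames, dtype=float))


# ---------------------------------------------------------------------------
# Preprocessing steps.
# ---------------------------------------------------------------------------


def split_stance_phases(
    video: PressureVideo, epsilon: float = 0.0
) -> list[StanceVideo]:
    """Split a recording at zero-pressure frames into stance segments.

    Frames whose total pressure is <= ``epsilon`` delimit segments (the
    swing phase registers no pressure); each maximal run of frames above
    the threshold becomes one :class:`StanceVideo`, in temporal order.
    An all-zero video yields an empty list.
    """
    totals = video.frame_totals()
    active = totals > epsilon
    segments: list[StanceVideo] = []
    start = None
    for i, on in enumerate([*active, False]):
        if on and start is None:
            start = i
        elif not on and start is not None:
            segments.append(
                StanceVideo(
                    video.frames[start:i].copy(),
                    frame_rate=video.frame_rate,
                    cell_area=video.cell_area,
                    segment_index=len(segments),
                )
            )
            start = None
    return segments


def select_representatives(
    segments: Sequence[StanceVideo],
    n_groups: int = 5,
    rng_seed: int | np.random.Generator = 0,
) -> list[StanceVideo]:
    """Thin stance segments to one representative per temporal group.

    The segments are partitioned, in temporal order, into ``n_groups``
    contiguous groups as equal in size as possible (any remainder goes to
    the earliest groups); one segment is drawn uniformly from each group
    with the seeded generator.
    """
    if len(segments) < n_groups:
        raise ValueError(
            f"need at least {n_groups} segments to form {n_groups} groups, "
            f"got {len(segments)}"
        )
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    groups = np.array_split(np.arange(len(segments)), n_groups)
    return [segments[int(rng.choice(g))] for g in groups]


def crop_white_border(video: PressureVideo) -> PressureVideo:
    """Remove border rows/columns that receive no pressure in any frame.

    Only leading and trailing all-zero rows/columns are removed; the
    output is the bounding box of the union of non-zero cells across all
    frames, so interior all-zero rows/columns survive.
    """
    union = video.frames.any(axis=0)
    if not union.any():
        raise ValueError("nothing to crop: video is all zero")
    rows = np.flatnonzero(union.any(axis=1))
    cols = np.flatnonzero(union.any(axis=0))
    cropped = video.frames[:, rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    return replace(video, frames=cropped.copy())


def _overlap_weights(n_src: int, n_tgt: int) -> np.ndarray:
    """(n_src, n_tgt) matrix of the fraction of source cell i inside target bin j.

    The source axis is scaled onto the target axis; rows sum to 1 so each
    source cell's force is fully distributed.
    """
    scale = n_tgt / n_src
    src_edges = np.arange(n_src + 1) * scale  # in target coordinates
    w = np.zeros((n_src, n_tgt))
    for i in range(n_src):
        lo, hi = src_edges[i], src_edges[i + 1]
        j0, j1 = int(np.floor(lo)), int(np.ceil(hi))
        for j in range(j0, min(j1, n_tgt)):
            w[i, j] = max(0.0, min(hi, j + 1) - max(lo, j)) / scale
    return w


def downsample(
    video: PressureVideo, target: tuple[int, int] = (20, 7)
) -> PressureVideo:
    """Rebin a video to ``target`` = (H_t, W_t) conserving force.

    Each source cell carries force = pressure x cell area; force is
    distributed over target bins in proportion to geometric overlap and
    target pressure is accumulated force / bin area (P = F/A). Uniform
    fields are fixed points and total force per frame is conserved.
    """
    h_t, w_t = target
    if h_t < 1 or w_t < 1:
        raise ValueError("target dims must be >= 1")
    h_s, w_s = video.shape
    if (h_s, w_s) == (h_t, w_t):
        return video
    wy = _overlap_weights(h_s, h_t)
    wx = _overlap_weights(w_s, w_t)
    force = video.frames * video.cell_area
    tgt_force = np.einsum("nhw,hi,wj->nij", force, wy, wx)
    tgt_area = video.cell_area * (h_s * w_s) / (h_t * w_t)
    return replace(video, frames=tgt_force / tgt_area, cell_area=tgt_area)


def preprocess_recording(
    video: PressureVideo,
    n_groups: int = 5,
    target: tuple[int, int] = (20, 7),
    rng_seed: int | np.random.Generator = 0,
    epsilon: float = 0.0,
) -> list[StanceVideo]:
    """Full pipeline: split, select representatives, crop, downsample."""
    segments = split_stance_phases(video, epsilon=epsilon)
    chosen = select_representatives(segments, n_groups=n_groups, rng_seed=rng_seed)
    out = []
    for seg in chosen:
        small = downsample(crop_white_border(seg), target=target)
        out.append(
            StanceVideo(
                small.frames,
                frame_rate=small.frame_rate,
                cell_area=small.cell_area,
                segment_index=seg.segment_index,
            )
        )
    return out
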