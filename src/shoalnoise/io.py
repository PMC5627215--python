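"""Trajectory ingest, validation, gap repair and trial segmentation.

Trajectory files are the common export of video-tracking tools: plain
delimited text with a header ``frame,fish_id,x,y`` and one row per fish per
frame.  Positions are converted to cm via a single ``cm_per_pixel`` scalar
and stored on a dense per-trial frame grid with NaN marking tracking
dropouts.  Frame indices are 0-based and trial halves are the half-open
intervals ``[start, boundary)`` and ``[boundary, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .arena import ArenaSpec, regular_octagon

__all__ = [
    "TrialDesign",
    "TrajectoryDataset",
    "TrajectoryFormatError",
    "TrajectoryIntegrityError",
    "DesignMismatchError",
    "read_trajectories",
    "write_trajectories",
    "interpolate_gaps",
    "split_halves",
    "gap_statistics",
]

TREATMENTS = ("ambient", "pile_driving")


class TrajectoryFormatError(ValueError):
    """Input file does not follow the frame,fish_id,x,y layout."""


class TrajectoryIntegrityError(ValueError):
    """Duplicate or inconsistent rows in a trajectory file."""


class DesignMismatchError(ValueError):
    """File contents disagree with the trial design (e.g. fish count)."""


@dataclass(frozen=True)
class TrialDesign:
    """Metadata for one trial: what was played, when, and the geometry."""

    trial_id: str
    treatment: str
    fps: float
    half_boundary: int
    n_fish: int = 4
    cm_per_pixel: float = 1.0
    arena: Optional[ArenaSpec] = None

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment must be one of {TREATMENTS}, got {self.treatment!r}")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.n_fish < 2:
            raise ValueError("need at least 2 fish")
        if self.cm_per_pixel <= 0:
            raise ValueError("cm_per_pixel must be positive")


@dataclass
class TrajectoryDataset:
    """Positions of all fish in one trial (or trial half), in cm.

    ``positions`` has shape (n_frames, n_fish, 2) on the dense frame grid
    ``frames``; missing fixes are NaN.  ``half_boundary`` is the absolute
    frame index at which playback starts.
    """

    trial_id: str
    positions: np.ndarray
    frames: np.ndarray
    fish_ids: np.ndarray
    fps: float
    arena: ArenaSpec
    half_boundary: Optional[int]
    treatment: str
    half: Optional[str] = None  # None (whole trial), "first" or "second"
    n_interpolated: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.frames = np.asarray(self.frames, dtype=int)
        self.fish_ids = np.asarray(self.fish_ids)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValueError("positions must have shape (n_frames, n_fish, 2)")
        if self.positions.shape[0] != self.frames.size:
            raise ValueError("frames and positions disagree in length")
        if self.positions.shape[1] != self.fish_ids.size:
            raise ValueError("fish_ids and positions disagree in fish count")
        if self.n_fish < 2:
            raise ValueError("need at least 2 fish")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if np.any(np.diff(self.frames) != 1):
            raise ValueError("frames must be a contiguous 0-based range")
        if self.half_boundary is not None and self.half is None:
            lo, hi = self.frames[0], self.frames[-1]
            if not (lo < self.half_boundary <= hi):
                raise ValueError(
                    f"half_boundary {self.half_boundary} not strictly inside "
                    f"frame range [{lo}, {hi}]"
                )
        finite = ~np.isnan(self.positions).any(axis=2)
        if not np.all(self.arena.contains(self.positions[finite])):
            raise ValueError("positions outside the arena polygon")

    @property
    def n_fish(self) -> int:
        return self.positions.shape[1]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def scaled(self, factor: float) -> "TrajectoryDataset":
        """Rescale all lengths by ``factor`` (new arena included)."""
        arena = ArenaSpec(self.arena.vertices * factor, self.arena.narrowest_width * factor)
        return replace(self, positions=self.positions * factor, arena=arena)

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy (frame, fish_id, x, y) rows; missing fixes are omitted."""
        rows = []
        for j, fid in enumerate(self.fish_ids):
            ok = ~np.isnan(self.positions[:, j]).any(axis=1)
            rows.append(
                pd.DataFrame(
                    {
                        "frame": self.frames[ok],
                        "fish_id": fid,
                        "x": self.positions[ok, j, 0],
                        "y": self.positions[ok, j, 1],
                    }
                )
            )
        df = pd.concat(rows, ignore_index=True)
        return df.sort_values(["fish_id", "frame"], kind="stable").reset_index(drop=True)


def _dense_grid(df: pd.DataFrame, fish_ids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = int(df["frame"].min()), int(df["frame"].max())
    frames = np.arange(lo, hi + 1)
    pos = np.full((frames.size, fish_ids.size, 2), np.nan)
    for j, fid in enumerate(fish_ids):
        sub = df[df["fish_id"] == fid]
        idx = sub["frame"].to_numpy(dtype=int) - lo
        pos[idx, j, 0] = sub["x"].to_numpy(dtype=float)
        pos[idx, j, 1] = sub["y"].to_numpy(dtype=float)
    return frames, pos


def read_trajectories(
    path: str | Path,
    design: TrialDesign,
    cm_per_pixel: Optional[float] = None,
) -> TrajectoryDataset:
    """Read a tracked-trajectory CSV and validate it against the design.

    Returns the dataset in cm with per-fish gap statistics in
    ``dataset.meta["gaps"]``.
    """
    scale = design.cm_per_pixel if cm_per_pixel is None else cm_per_pixel
    if scale <= 0:
        raise ValueError("cm_per_pixel must be positive")
    df = pd.read_csv(path)
    required = ["frame", "fish_id", "x", "y"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TrajectoryFormatError(f"missing required column(s): {', '.join(missing)}")
    if df["frame"].lt(0).any() or (df["frame"] != df["frame"].astype(int)).any():
        raise TrajectoryFormatError("frame indices must be non-negative integers")
    dup = df.duplicated(subset=["fish_id", "frame"])
    if dup.any():
        bad = df.loc[dup, ["fish_id", "frame"]].iloc[0]
        raise TrajectoryIntegrityError(
            f"duplicate (fish_id, frame) row: fish {bad['fish_id']}, frame {int(bad['frame'])}"
        )
    fish_ids = np.sort(df["fish_id"].unique())
    if fish_ids.size != design.n_fish:
        raise DesignMismatchError(
            f"file has {fish_ids.size} fish but design specifies {design.n_fish}"
        )
    frames, pos = _dense_grid(df, fish_ids)
    pos *= scale
    arena = design.arena if design.arena is not None else regular_octagon()
    ds = TrajectoryDataset(
        trial_id=design.trial_id,
        positions=pos,
        frames=frames,
        fish_ids=fish_ids,
        fps=design.fps,
        arena=arena,
        half_boundary=design.half_boundary,
        treatment=design.treatment,
    )
    ds.meta["gaps"] = gap_statistics(ds)
    return ds


def write_trajectories(ds: TrajectoryDataset, path: str | Path) -> None:
    """Write the CSV dialect ``read_trajectories`` reads (round-trips exactly)."""
    df = ds.to_dataframe()
    # str(float) round-trips in Python 3, keeping read->write->read bit exact
    df.to_csv(path, index=False)


def gap_statistics(ds: TrajectoryDataset) -> pd.DataFrame:
    """Per-fish gap report: one row per internal run of missing frames."""
    records = []
    for j, fid in enumerate(ds.fish_ids):
        missing = np.isnan(ds.positions[:, j]).any(axis=1)
        if not missing.any():
            continue
        padded = np.concatenate([[False], missing, [False]])
        starts = np.flatnonzero(~padded[:-1] & padded[1:])
        ends = np.flatnonzero(padded[:-1] & ~padded[1:])
        for s, e in zip(starts, ends):
            records.append(
                {
                    "fish_id": fid,
                    "start_frame": int(ds.frames[0] + s),
                    "length": int(e - s),
                    "at_edge": bool(s == 0 or e == ds.n_frames),
                }
            )
    return pd.DataFrame(records, columns=["fish_id", "start_frame", "length", "at_edge"])


def interpolate_gaps(ds: TrajectoryDataset, max_gap: int) -> TrajectoryDataset:
    """Fill internal tracking gaps of length <= ``max_gap`` frames linearly.

    Longer gaps, and gaps touching the start or end of the series, are left
    as NaN (no extrapolation); downstream metrics skip them pairwise.  The
    number of interpolated frames is recorded on the returned dataset.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    pos = ds.positions.copy()
    n_filled = 0
    gaps = gap_statistics(ds)
    for _, g in gaps.iterrows():
        if g["at_edge"] or g["length"] > max_gap:
            continue
        j = int(np.flatnonzero(ds.fish_ids == g["fish_id"])[0])
        s = int(g["start_frame"] - ds.frames[0])
        e = s + int(g["length"])
        p0, p1 = pos[s - 1, j], pos[e, j]
        w = (np.arange(1, e - s + 1)) / (e - s + 1)
        pos[s:e, j] = p0[None, :] + w[:, None] * (p1 - p0)[None, :]
        n_filled += e - s
    out = replace(ds, positions=pos, n_interpolated=ds.n_interpolated + n_filled)
    out.meta = dict(ds.meta)
    out.meta["gaps_after_repair"] = gap_statistics(out)
    return out


def split_halves(ds: TrajectoryDataset) -> tuple[TrajectoryDataset, TrajectoryDataset]:
    """Partition a trial at its half boundary into (first, second) halves."""
    if ds.half_boundary is None:
        raise ValueError("dataset has no half_boundary set")
    b = int(ds.half_boundary)
    lo, hi = int(ds.frames[0]), int(ds.frames[-1])
    if not (lo < b <= hi):
        raise ValueError(f"half_boundary {b} outside frame range [{lo}, {hi}]")
    cut = b - lo
    first = replace(
        ds, positions=ds.positions[:cut], frames=ds.frames[:cut], half="first"
    )
    second = replace(
        ds, positions=ds.positions[cut:], frames=ds.frames[cut:], half="second"
    )
    first.meta = dict(ds.meta)
    second.meta = dict(ds.meta)
    return first, second
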