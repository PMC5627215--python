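"""Per-fish speed and heading series derived from tracked positions.

Direction is operationalised as the bearing of the velocity vector (only
centroid tracks are available from the tracking stage, so body orientation
is not observable).  Velocities come from central differences on lightly
boxcar-smoothed positions; below a speed threshold the heading is treated
as undefined, since direction estimated from sub-noise displacements is
meaningless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import TrajectoryDataset

__all__ = ["KinematicSeries", "compute_kinematics", "median_speed"]


@dataclass
class KinematicSeries:
    """Speed (cm/s), unit heading and validity mask for one fish."""

    fish_id: object
    frames: np.ndarray
    speed: np.ndarray        # cm/s, NaN where position data are missing
    heading: np.ndarray      # (n, 2) unit vectors, NaN where invalid
    valid: np.ndarray        # heading defined (speed >= threshold, data present)
    fps: float

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.heading[self.valid], axis=1)
        if norms.size and not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("valid headings must be unit vectors")


def _boxcar(pos: np.ndarray, window: int) -> np.ndarray:
    """Centred NaN-aware moving average per coordinate (window shrinks at edges)."""
    if window <= 1:
        return pos
    df = pd.DataFrame(pos)
    sm = df.rolling(window, center=True, min_periods=1).mean().to_numpy()
    sm[np.isnan(pos)] = np.nan  # smoothing must not invent missing fixes
    return sm


def compute_kinematics(
    ds: TrajectoryDataset,
    smoothing_window: int = 5,
    heading_threshold: float = 0.5,
) -> list[KinematicSeries]:
    """Derive speed and heading for every fish in the dataset.

    Central differences on smoothed positions, one-sided at the first and
    last valid frames; heading is the unit velocity where speed >=
    ``heading_threshold`` cm/s.
    """
    if ds.fps <= 0:
        raise ValueError("fps must be positive")
    if ds.n_frames < 3:
        raise ValueError("need at least 3 frames to differentiate")
    dt = 1.0 / ds.fps
    out = []
    for j, fid in enumerate(ds.fish_ids):
        p = _boxcar(ds.positions[:, j], smoothing_window)
        ok = ~np.isnan(p).any(axis=1)
        if ok.sum() < 3:
            raise ValueError(f"fish {fid}: fewer than 3 valid frames")
        v = np.full_like(p, np.nan)
        # central difference wherever both neighbours are present
        both = ok[:-2] & ok[2:]
        idx = np.flatnonzero(both) + 1
        v[idx] = (p[idx + 1] - p[idx - 1]) / (2 * dt)
        # one-sided fallback (covers endpoints and gap borders)
        fwd = np.flatnonzero(ok[:-1] & ok[1:] & np.isnan(v[:-1]).any(axis=1))
        v[fwd] = (p[fwd + 1] - p[fwd]) / dt
        bwd = np.flatnonzero(ok[:-1] & ok[1:] & np.isnan(v[1:]).any(axis=1)) + 1
        v[bwd] = (p[bwd] - p[bwd - 1]) / dt
        v[~ok] = np.nan
        speed = np.linalg.norm(v, axis=1)
        valid = np.isfinite(speed) & (speed >= heading_threshold)
        heading = np.full_like(p, np.nan)
        heading[valid] = v[valid] / speed[valid, None]
        out.append(
            KinematicSeries(
                fish_id=fid,
                frames=ds.frames.copy(),
                speed=speed,
                heading=heading,
                valid=valid,
                fps=ds.fps,
            )
        )
    return out


def median_speed(ks: KinematicSeries) -> float:
    """Median speed (cm/s) over frames with data present."""
    s = ks.speed[np.isfinite(ks.speed)]
    if s.size == 0:
        raise ValueError("no valid speed frames")
    return float(np.median(s))
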