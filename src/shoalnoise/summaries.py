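"""Reduce a trial to the tidy per-fish-per-half response table.

Each fish contributes one row per trial half with every response analysed
downstream: cohesion (mean centroid distance, modal NND), relative
positioning (perpendicular/parallel offsets, bearings split front/behind),
directional order (mean heading difference), and movement dynamics (median
speed, peak speed/direction cross-correlations with the modal nearest
neighbour and the direction delay).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import pair_dynamics_summary
from .io import TrajectoryDataset, split_halves
from .kinematics import compute_kinematics, median_speed
from .metrics import (
    PairwiseGeometry,
    centroid_distance,
    modal_nnd,
    nearest_neighbour_geometry,
)

__all__ = ["MetricParams", "summarize_half", "summarize_trial", "RESPONSE_COLUMNS"]

RESPONSE_COLUMNS = [
    "mean_centroid_dist",
    "modal_nnd",
    "mean_perp",
    "mean_para",
    "mean_bearing_front",
    "mean_bearing_behind",
    "mean_heading_diff",
    "median_speed",
    "max_speed_corr",
    "max_dir_corr",
    "dir_delay_s",
    "speed_delay_s_excluded",
]


@dataclass(frozen=True)
class MetricParams:
    """Tunable metric parameters surfaced in the pipeline config."""

    smoothing_window: int = 5
    heading_threshold: float = 0.5   # cm/s
    nnd_bin_width: float = 0.5       # cm
    nnd_min_frames: int = 50
    max_lag: float = 2.0             # s
    min_overlap: int = 100           # frames


def _nanmean(x: np.ndarray) -> float:
    x = x[np.isfinite(x)]
    return float(np.mean(x)) if x.size else np.nan


def summarize_half(
    ds: TrajectoryDataset, params: MetricParams = MetricParams()
) -> tuple[pd.DataFrame, list[PairwiseGeometry]]:
    """One response row per fish for a single trial half."""
    ks = compute_kinematics(ds, params.smoothing_window, params.heading_threshold)
    _, cent_means, _ = centroid_distance(ds)
    pgs = nearest_neighbour_geometry(ds, ks)
    dyn = pair_dynamics_summary(ds, ks, pgs, params.max_lag, params.min_overlap)
    dyn = dyn.set_index("fish")
    rows = []
    for j, (k, pg) in enumerate(zip(ks, pgs)):
        front = pg.bearing[np.isfinite(pg.bearing) & (pg.side == "front")]
        behind = pg.bearing[np.isfinite(pg.bearing) & (pg.side == "behind")]
        rows.append(
            {
                "trial": ds.trial_id,
                "fish": k.fish_id,
                "treatment": ds.treatment,
                "half": ds.half if ds.half is not None else "all",
                "mean_centroid_dist": float(cent_means[j]),
                "modal_nnd": modal_nnd(
                    pg.nnd, params.nnd_bin_width, params.nnd_min_frames
                ),
                "mean_perp": _nanmean(pg.perp_offset),
                "mean_para": _nanmean(pg.para_offset),
                "mean_bearing_front": _nanmean(front),
                "mean_bearing_behind": _nanmean(behind),
                "mean_heading_diff": _nanmean(pg.heading_diff),
                "median_speed": median_speed(k),
                "max_speed_corr": dyn.loc[k.fish_id, "max_speed_corr"],
                "max_dir_corr": dyn.loc[k.fish_id, "max_dir_corr"],
                "dir_delay_s": dyn.loc[k.fish_id, "dir_delay_s"],
                "speed_delay_s_excluded": dyn.loc[k.fish_id, "speed_delay_s_excluded"],
            }
        )
    return pd.DataFrame(rows), pgs


def summarize_trial(
    ds: TrajectoryDataset, params: MetricParams = MetricParams()
) -> tuple[pd.DataFrame, dict[str, list[PairwiseGeometry]]]:
    """Both halves of a trial; returns the response rows and the pairwise
    geometry per half (kept for the relative-position map)."""
    first, second = split_halves(ds)
    rows1, pg1 = summarize_half(first, params)
    rows2, pg2 = summarize_half(second, params)
    table = pd.concat([rows1, rows2], ignore_index=True)
    return table, {"first": pg1, "second": pg2}
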