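"""Spatial and directional organisation measures of the shoal.

Per fish and per trial half: distance to the shoal centroid, nearest-
neighbour distance (and its mode), the position of the nearest neighbour
relative to the focal fish's travel direction (bearing angle, side-by-side
and front-behind offsets), the heading difference between nearest
neighbours, and a focal-centred relative-position density map.

Angle conventions: the bearing angle is the unsigned angle between the
focal heading and the focal-to-neighbour vector, folded to [0, 180] degrees
(0 = neighbour dead ahead, 90 = directly beside, 180 = dead behind); the
heading difference is the unsigned angle between two headings, 0 = aligned,
180 = opposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import TrajectoryDataset
from .kinematics import KinematicSeries

__all__ = [
    "PairwiseGeometry",
    "RelativePositionMap",
    "centroid_distance",
    "nearest_neighbour_geometry",
    "modal_nnd",
    "heading_difference_summary",
    "relative_position_map",
]


@dataclass
class PairwiseGeometry:
    """Per-frame nearest-neighbour geometry for one focal fish.

    ``offset_right``/``offset_ahead`` are the signed components of the
    focal-to-neighbour vector across/along the focal heading (right-handed:
    +right is to the fish's right with y up); ``perp_offset``/``para_offset``
    are their absolute values, so perp^2 + para^2 = nnd^2 on frames where
    the heading is defined.
    """

    fish_id: object
    frames: np.ndarray
    neighbour_id: np.ndarray     # nearest neighbour per frame (-1 = none)
    nnd: np.ndarray              # cm; NaN where focal or all neighbours missing
    bearing: np.ndarray          # degrees [0, 180]; NaN where heading invalid
    side: np.ndarray             # "front" (bearing < 90) / "behind" / ""
    perp_offset: np.ndarray
    para_offset: np.ndarray
    offset_right: np.ndarray
    offset_ahead: np.ndarray
    heading_diff: np.ndarray     # degrees [0, 180]; needs both headings valid


def centroid_distance(ds: TrajectoryDataset) -> tuple[np.ndarray, np.ndarray, int]:
    """Distance of each fish to the shoal centroid.

    Returns ``(dist, per_fish_mean, n_skipped)`` where ``dist`` is
    (n_frames, n_fish) in cm (NaN where the fish is missing or fewer than
    two fish are present at the frame) and ``n_skipped`` counts skipped
    frames.
    """
    pos = ds.positions
    present = ~np.isnan(pos).any(axis=2)
    n_present = present.sum(axis=1)
    usable = n_present >= 2
    with np.errstate(invalid="ignore"):
        centroid = np.nanmean(pos, axis=1)
    dist = np.linalg.norm(pos - centroid[:, None, :], axis=2)
    dist[~usable, :] = np.nan
    dist[~present] = np.nan
    valid = np.isfinite(dist)
    counts = valid.sum(axis=0)
    sums = np.where(valid, dist, 0.0).sum(axis=0)
    means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return dist, means, int((~usable).sum())


def _pairwise_distances(pos: np.ndarray) -> np.ndarray:
    """(n_frames, n_fish, n_fish) Euclidean distances; NaN-safe via inf."""
    diff = pos[:, :, None, :] - pos[:, None, :, :]
    d = np.linalg.norm(diff, axis=3)
    n = pos.shape[1]
    d[:, np.arange(n), np.arange(n)] = np.inf
    d[np.isnan(d)] = np.inf
    return d


def nearest_neighbour_geometry(
    ds: TrajectoryDataset, ks: list[KinematicSeries]
) -> list[PairwiseGeometry]:
    """Nearest-neighbour geometry per focal fish.

    The nearest neighbour is re-assigned every frame by Euclidean distance
    (ties to the lower fish index).  Frames without a valid focal heading
    keep the NND but have no bearing/offset/heading-difference; frames with
    no neighbour present are skipped entirely.
    """
    pos = ds.positions
    T, n = pos.shape[:2]
    dists = _pairwise_distances(pos)
    nn_idx = np.argmin(dists, axis=2)          # ties -> lowest index
    nn_dist = np.take_along_axis(dists, nn_idx[:, :, None], axis=2)[:, :, 0]
    headings = np.stack([k.heading for k in ks], axis=1)   # (T, n, 2)
    hvalid = np.stack([k.valid for k in ks], axis=1)
    out = []
    t_idx = np.arange(T)
    for j in range(n):
        nb = nn_idx[:, j]
        has_nb = np.isfinite(nn_dist[:, j])
        nnd = np.where(has_nb, nn_dist[:, j], np.nan)
        d = pos[t_idx, nb] - pos[:, j]                     # focal -> neighbour
        h = headings[:, j]
        ok = hvalid[:, j] & has_nb
        ahead = np.einsum("ij,ij->i", d, h)
        right = d[:, 0] * h[:, 1] - d[:, 1] * h[:, 0]      # +ve to the right
        with np.errstate(invalid="ignore"):
            cosb = np.clip(ahead / np.where(nnd > 0, nnd, np.nan), -1.0, 1.0)
            bearing = np.degrees(np.arccos(cosb))
        bearing[~ok] = np.nan
        ahead = np.where(ok, ahead, np.nan)
        right = np.where(ok, right, np.nan)
        side = np.where(
            np.isnan(bearing), "", np.where(bearing < 90.0, "front", "behind")
        )
        hn = headings[t_idx, nb]
        both = ok & hvalid[t_idx, nb]
        cosd = np.clip(np.einsum("ij,ij->i", h, hn), -1.0, 1.0)
        hdiff = np.degrees(np.arccos(cosd))
        hdiff[~both] = np.nan
        out.append(
            PairwiseGeometry(
                fish_id=ds.fish_ids[j],
                frames=ds.frames.copy(),
                neighbour_id=np.where(has_nb, ds.fish_ids[nb], -1),
                nnd=nnd,
                bearing=bearing,
                side=side,
                perp_offset=np.abs(right),
                para_offset=np.abs(ahead),
                offset_right=right,
                offset_ahead=ahead,
                heading_diff=hdiff,
            )
        )
    return out


def modal_nnd(
    nnd_series: np.ndarray, bin_width: float = 0.5, min_frames: int = 50
) -> float:
    """Mode of the nearest-neighbour distance distribution.

    Fixed-width histogram over [0, max]; returns the centre of the fullest
    bin, ties resolved toward the smallest distance.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    x = np.asarray(nnd_series, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("empty nearest-neighbour distance series")
    if x.size < min_frames:
        raise ValueError(f"need at least {min_frames} valid frames, got {x.size}")
    n_bins = int(np.floor(x.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(x, bins=edges)
    k = int(np.argmax(counts))  # argmax takes the first maximal bin
    return float((edges[k] + edges[k + 1]) / 2)


def heading_difference_summary(pg: PairwiseGeometry) -> float:
    """Mean nearest-neighbour heading difference (degrees) over the half."""
    h = pg.heading_diff[np.isfinite(pg.heading_diff)]
    if h.size == 0:
        raise ValueError("no frames with both headings valid")
    return float(np.mean(h))


@dataclass
class RelativePositionMap:
    """Density of nearest-neighbour positions around the focal fish.

    The grid lives in the focal-centred, heading-aligned frame (x = right of
    travel, y = ahead); ``grid[iy, ix]`` with both axes given by
    ``edges``.  The density is a probability mass function; smoothing
    renormalises so the total mass stays 1.
    """

    grid: np.ndarray
    edges: np.ndarray
    bin_size: float
    smoothing_sigma: float
    n_frames: int


def relative_position_map(
    pgs: list[PairwiseGeometry],
    bin_size: float = 1.0,
    extent: float = 30.0,
    sigma: float = 6.0,
) -> RelativePositionMap:
    """Heading-aligned nearest-neighbour density map, Gaussian smoothed.

    ``sigma`` is in grid cells (the conventional display smoothing for
    these maps); pass ``sigma=0`` for the raw histogram.
    """
    rights = np.concatenate([pg.offset_right for pg in pgs])
    aheads = np.concatenate([pg.offset_ahead for pg in pgs])
    ok = np.isfinite(rights) & np.isfinite(aheads)
    if ok.sum() == 0:
        raise ValueError("no valid frames for relative position map")
    edges = np.arange(-extent, extent + bin_size / 2, bin_size)
    grid, _, _ = np.histogram2d(aheads[ok], rights[ok], bins=[edges, edges])
    total = grid.sum()
    if total == 0:
        raise ValueError("all offsets fall outside the map extent")
    grid /= total
    if sigma > 0:
        grid = ndimage.gaussian_filter(grid, sigma=sigma, mode="constant")
        grid /= grid.sum()  # renormalise mass clipped at the map border
    return RelativePositionMap(
        grid=grid,
        edges=edges,
        bin_size=bin_size,
        smoothing_sigma=sigma,
        n_frames=int(ok.sum()),
    )
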