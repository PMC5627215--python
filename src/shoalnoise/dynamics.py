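"""Nearest-neighbour cross-correlation dynamics.

How strongly, and with what time delay, pairs of fish copy each other's
speed and direction changes.  For a pair (i, j) and integer frame lag tau,
the speed curve is the Pearson correlation between speed_i(t) and
speed_j(t + tau); the direction curve is the mean dot product of the two
unit headings at that relative shift (the normalised-velocity correlation
used for leader-follower analysis of bird flocks).  A positive delay at
the peak means fish j follows fish i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import TrajectoryDataset
from .kinematics import KinematicSeries
from .metrics import PairwiseGeometry

__all__ = [
    "CrossCorrResult",
    "speed_crosscorr",
    "direction_crosscorr",
    "modal_neighbour",
    "pair_dynamics_summary",
]


@dataclass
class CrossCorrResult:
    """Lag-indexed correlation curve with its peak and time delay."""

    lags: np.ndarray        # frame offsets, symmetric window
    curve: np.ndarray       # correlation per lag; NaN where undefined/dropped
    n_overlap: np.ndarray   # frames contributing per lag
    peak: float             # max of curve over reported lags
    delay_frames: int       # lag at the peak (ties: smallest |lag|, - before +)
    fps: float

    @property
    def delay(self) -> float:
        """Delay at the peak in seconds."""
        return self.delay_frames / self.fps


def _pick_peak(lags: np.ndarray, curve: np.ndarray) -> tuple[float, int]:
    ok = np.isfinite(curve)
    if not ok.any():
        raise ValueError("correlation undefined at every lag")
    peak = float(np.max(curve[ok]))
    tied = ok & (curve >= peak - 1e-12)
    cand = lags[tied]
    order = np.lexsort((cand > 0, np.abs(cand)))
    return peak, int(cand[order[0]])


def _lagged_views(a: np.ndarray, b: np.ndarray, tau: int) -> tuple[np.ndarray, np.ndarray]:
    """Overlap of a(t) with b(t + tau)."""
    if tau >= 0:
        return (a[: a.shape[0] - tau], b[tau:]) if tau else (a, b)
    return a[-tau:], b[:tau]


def _all_lag_sums(x: np.ndarray, y: np.ndarray, L: int):
    """For every lag tau in [-L, L]: overlap count, sum of x, y, x^2, y^2 and
    sum of x(t) * y(t + tau), computed with prefix sums (NaN-free input)."""
    n = x.size
    lags = np.arange(-L, L + 1)
    m = n - np.abs(lags)
    cx = np.concatenate([[0.0], np.cumsum(x)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cx2 = np.concatenate([[0.0], np.cumsum(x * x)])
    cy2 = np.concatenate([[0.0], np.cumsum(y * y)])
    pos = lags >= 0
    sx = np.where(pos, cx[np.minimum(m, n)] - cx[0], cx[n] - cx[n - m])
    sx2 = np.where(pos, cx2[np.minimum(m, n)] - cx2[0], cx2[n] - cx2[n - m])
    sy = np.where(pos, cy[n] - cy[n - m], cy[np.minimum(m, n)] - cy[0])
    sy2 = np.where(pos, cy2[n] - cy2[n - m], cy2[np.minimum(m, n)] - cy2[0])
    # S(tau) = sum_t x[t] y[t+tau] = np.correlate(y, x, "full")[n - 1 + tau]
    sxy = np.correlate(y, x, mode="full")[n - 1 + lags]
    return lags, m, sx, sy, sx2, sy2, sxy


def speed_crosscorr(
    speed_i: np.ndarray,
    speed_j: np.ndarray,
    max_lag: float,
    fps: float,
    min_overlap: int = 100,
) -> CrossCorrResult:
    """Per-lag Pearson cross-correlation of two speed series.

    Lags where either series is constant over the overlap, or the overlap is
    below ``min_overlap`` frames, are dropped; if every lag drops the pair is
    uninformative and an error is raised.
    """
    si = np.asarray(speed_i, dtype=float)
    sj = np.asarray(speed_j, dtype=float)
    if si.shape != sj.shape:
        raise ValueError("series must share a frame index")
    L = int(round(max_lag * fps))
    if np.all(np.isfinite(si)) and np.all(np.isfinite(sj)) and si.size > L:
        lags, m, sx, sy, sx2, sy2, sxy = _all_lag_sums(si, sj, L)
        with np.errstate(invalid="ignore", divide="ignore"):
            vx = sx2 - sx * sx / m
            vy = sy2 - sy * sy / m
            curve = (sxy - sx * sy / m) / np.sqrt(vx * vy)
        tiny = np.sqrt(np.maximum(vx, 0) * np.maximum(vy, 0)) <= 1e-12 * m
        curve[tiny] = np.nan
        curve[m < max(min_overlap, 2)] = np.nan
        n_overlap = m
    else:
        lags = np.arange(-L, L + 1)
        curve = np.full(lags.size, np.nan)
        n_overlap = np.zeros(lags.size, dtype=int)
        for idx, tau in enumerate(lags):
            a, b = _lagged_views(si, sj, int(tau))
            ok = np.isfinite(a) & np.isfinite(b)
            n = int(ok.sum())
            n_overlap[idx] = n
            if n < max(min_overlap, 2):
                continue
            x, y = a[ok], b[ok]
            sdx, sdy = x.std(), y.std()
            if sdx == 0 or sdy == 0:
                continue  # correlation undefined for a constant series
            curve[idx] = float(np.mean((x - x.mean()) * (y - y.mean())) / (sdx * sdy))
    peak, delay = _pick_peak(lags, curve)
    return CrossCorrResult(lags, curve, n_overlap, peak, delay, fps)


def direction_crosscorr(
    heading_i: np.ndarray,
    heading_j: np.ndarray,
    max_lag: float,
    fps: float,
    min_overlap: int = 100,
) -> CrossCorrResult:
    """Directional cross-correlation: mean heading dot product per lag."""
    hi = np.asarray(heading_i, dtype=float)
    hj = np.asarray(heading_j, dtype=float)
    if hi.shape != hj.shape or hi.ndim != 2 or hi.shape[1] != 2:
        raise ValueError("headings must be matching (n, 2) arrays")
    L = int(round(max_lag * fps))
    if np.all(np.isfinite(hi)) and np.all(np.isfinite(hj)) and hi.shape[0] > L:
        n = hi.shape[0]
        lags = np.arange(-L, L + 1)
        m = n - np.abs(lags)
        # sum_t h_i(t) . h_j(t+tau) is a pair of 1-D cross-correlations
        sdot = (
            np.correlate(hj[:, 0], hi[:, 0], mode="full")[n - 1 + lags]
            + np.correlate(hj[:, 1], hi[:, 1], mode="full")[n - 1 + lags]
        )
        curve = sdot / m
        curve[m < max(min_overlap, 1)] = np.nan
        n_overlap = m
    else:
        lags = np.arange(-L, L + 1)
        curve = np.full(lags.size, np.nan)
        n_overlap = np.zeros(lags.size, dtype=int)
        for idx, tau in enumerate(lags):
            a, b = _lagged_views(hi, hj, int(tau))
            ok = np.isfinite(a).all(axis=1) & np.isfinite(b).all(axis=1)
            nvalid = int(ok.sum())
            n_overlap[idx] = nvalid
            if nvalid < max(min_overlap, 1):
                continue
            curve[idx] = float(np.mean(np.einsum("ij,ij->i", a[ok], b[ok])))
    peak, delay = _pick_peak(lags, curve)
    return CrossCorrResult(lags, curve, n_overlap, peak, delay, fps)


def modal_neighbour(pg: PairwiseGeometry) -> object:
    """Most frequent nearest neighbour over the half (ties to lower id)."""
    ids = pg.neighbour_id[np.isfinite(pg.nnd)]
    ids = ids[ids != -1]
    if ids.size == 0:
        raise ValueError(f"fish {pg.fish_id}: no frames with a neighbour")
    vals, counts = np.unique(ids, return_counts=True)
    return vals[np.argmax(counts)]  # np.unique sorts, argmax takes first -> lower id


def pair_dynamics_summary(
    ds: TrajectoryDataset,
    ks: list[KinematicSeries],
    pgs: list[PairwiseGeometry],
    max_lag: float = 2.0,
    min_overlap: int = 100,
) -> pd.DataFrame:
    """Per-fish movement-dynamics summary against the modal nearest neighbour.

    One pair per focal fish per half: the cross-correlations are computed
    over the whole half against the most frequent nearest neighbour.  Speed
    delays are reported but flagged as excluded from inference (speeds are
    near-synchronous, so their delays carry no signal); direction delays
    are analysed.
    """
    by_id = {k.fish_id: k for k in ks}
    rows = []
    for pg in pgs:
        rec: dict = {"fish": pg.fish_id}
        try:
            nb = modal_neighbour(pg)
            ki, kj = by_id[pg.fish_id], by_id[nb]
            sc = speed_crosscorr(ki.speed, kj.speed, max_lag, ds.fps, min_overlap)
            hi = np.where(ki.valid[:, None], ki.heading, np.nan)
            hj = np.where(kj.valid[:, None], kj.heading, np.nan)
            dc = direction_crosscorr(hi, hj, max_lag, ds.fps, min_overlap)
        except (ValueError, KeyError) as err:
            rec.update(
                modal_neighbour=None, max_speed_corr=np.nan, max_dir_corr=np.nan,
                dir_delay_s=np.nan, speed_delay_s_excluded=np.nan, error=str(err),
            )
            rows.append(rec)
            continue
        rec.update(
            modal_neighbour=nb,
            max_speed_corr=sc.peak,
            max_dir_corr=dc.peak,
            dir_delay_s=dc.delay,
            speed_delay_s_excluded=sc.delay,
            error="",
        )
        rows.append(rec)
    return pd.DataFrame(rows)
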