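"""Synthetic shoal simulator with known ground truth.

A discrete-time zonal model stands in for live fish: each individual is
hard-repelled by too-close neighbours, aligns with neighbours in an
alignment annulus and is attracted toward the local centroid, with
wrapped-Gaussian turning noise; speeds follow an AR(1) process around a
preferred speed with a shared group component (so neighbours' speeds are
correlated, as in a real shoal).  One designated follower copies the mean
heading of the rest of the group with a fixed delay, giving the
cross-correlation stage a known leader-follower lag to recover.  Leaders
ignore the follower in their alignment term so that the built-in lag stays
identifiable ground truth.

The default configuration emulates the playback-experiment design: groups
of 4 fish in an octagonal arena of narrowest width 105 cm, two consecutive
trial halves, with a disruption (the "playback") applied in the second
half that weakens alignment and attraction, slows the fish, and raises
noise.  Desk-scale defaults (15 fps, 60 s halves) keep simulation studies
fast; the full-scale design (59 fps, 300 s halves) is available by config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from numba import njit

from .arena import ArenaSpec, regular_octagon
from .io import TrajectoryDataset

__all__ = [
    "DisruptionSpec",
    "SimulationConfig",
    "simulate_trial",
    "generate_experiment",
    "DEFAULT_AMBIENT_SPEC",
    "DEFAULT_PILE_SPEC",
]


@dataclass(frozen=True)
class DisruptionSpec:
    """Multipliers applied to the simulator during the playback half."""

    speed_mult: float = 1.0
    alignment_mult: float = 1.0
    attraction_mult: float = 1.0
    noise_mult: float = 1.0

    def __post_init__(self) -> None:
        for name in ("speed_mult", "alignment_mult", "attraction_mult", "noise_mult"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def is_identity(self) -> bool:
        return all(
            getattr(self, n) == 1.0
            for n in ("speed_mult", "alignment_mult", "attraction_mult", "noise_mult")
        )


# Calibration of the two playback treatments: both perturb the shoal, the
# pile-driving playback much more strongly (weaker alignment/attraction,
# slower swimming, noisier turning).
DEFAULT_AMBIENT_SPEC = DisruptionSpec(0.9, 0.95, 0.95, 1.1)
DEFAULT_PILE_SPEC = DisruptionSpec(0.6, 0.6, 0.7, 1.5)


@dataclass(frozen=True)
class SimulationConfig:
    """Zonal-model parameters; lengths in cm, times in s, angles in rad."""

    n_fish: int = 4
    fps: float = 15.0
    half_duration: float = 60.0
    arena: ArenaSpec = field(default_factory=regular_octagon)
    r_repulsion: float = 6.0       # ~ 2/3 body length exclusion zone
    r_alignment: float = 20.0      # ~ 2 body lengths
    r_attraction: float = 60.0
    w_alignment: float = 1.2
    w_attraction: float = 0.5
    heading_inertia: float = 1.5
    preferred_speed: float = 12.0  # ~ 1.2 body lengths / s cruise
    speed_noise: float = 2.0       # stationary sd of the fast individual AR term
    group_speed_noise: float = 3.0  # stationary sd of the shared fast AR term
    speed_ar: float = 0.9          # fast individual persistence (tau ~ 0.6 s)
    group_speed_ar: float = 0.1    # shared term is near-white: couples speeds
                                   # instant-to-instant without slow group drift
    indiv_speed_sd: float = 2.0    # sd of each fish's slowly drifting speed offset
    indiv_speed_tau: float = 20.0  # s; persistent individual differences
    heading_noise: float = 0.18    # per-step turning noise sd
    cohesion_drift_sd: float = 0.3   # sd of log attraction-weight drift (shared)
    cohesion_drift_tau: float = 15.0  # s; slow shared cohesion state
    follower_lag: int = 3          # frames
    follower_weight: float = 2.5
    follower_inertia: float = 0.3
    wall_buffer: float = 12.0
    wall_weight: float = 2.5
    burn_in: float = 5.0           # s discarded before the first half
    disruption: DisruptionSpec = field(default_factory=DisruptionSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.r_repulsion < self.r_alignment < self.r_attraction):
            raise ValueError("zone radii must satisfy repulsion < alignment < attraction")
        if self.n_fish < 2:
            raise ValueError("need at least 2 fish")
        if self.fps <= 0 or self.half_duration <= 0:
            raise ValueError("fps and half_duration must be positive")
        for name in ("speed_noise", "group_speed_noise", "heading_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.follower_lag < 0:
            raise ValueError("follower_lag must be >= 0")
        if not 0 <= self.speed_ar < 1:
            raise ValueError("speed_ar must be in [0, 1)")

    @property
    def half_frames(self) -> int:
        return int(round(self.half_duration * self.fps))


@njit(cache=False)
def _simulate_core(
    pos, head, n_steps, n_fish, dt,
    normals, wall_offsets,
    r_rep, r_align, r_attr,
    w_align_t, w_attr_t, sigma_t, pref_t, e_sd_t,
    inertia, wall_buffer, wall_weight,
    follower, lag, w_follow_t, inertia_follow,
    speed_ar, g_series, offset, dphi, dspd, e0,
):  # pragma: no cover - exercised via simulate_trial
    e = e0.copy()
    ar_innov = np.sqrt(1.0 - speed_ar * speed_ar)
    desired = np.empty((n_fish, 2))
    escaped = 0
    for t in range(n_steps - 1):
        for i in range(n_fish):
            hx, hy = head[t, i, 0], head[t, i, 1]
            # nearest neighbour and zone accumulators
            nn_d = 1e18
            nn_j = -1
            ax = ay = 0.0   # alignment
            cx = cy = 0.0   # attraction centroid
            n_al = 0
            n_at = 0
            for j in range(n_fish):
                if j == i:
                    continue
                dx = pos[t, j, 0] - pos[t, i, 0]
                dy = pos[t, j, 1] - pos[t, i, 1]
                d = np.sqrt(dx * dx + dy * dy)
                if d < nn_d:
                    nn_d = d
                    nn_j = j
                if r_rep < d <= r_align and not (i != follower and j == follower):
                    ax += head[t, j, 0]
                    ay += head[t, j, 1]
                    n_al += 1
                if d <= r_attr:
                    cx += pos[t, j, 0]
                    cy += pos[t, j, 1]
                    n_at += 1
            dx_des = 0.0
            dy_des = 0.0
            if nn_j >= 0 and nn_d < r_rep and nn_d > 1e-12:
                # hard repulsion overrides the social terms
                dx_des = 3.0 * (pos[t, i, 0] - pos[t, nn_j, 0]) / nn_d
                dy_des = 3.0 * (pos[t, i, 1] - pos[t, nn_j, 1]) / nn_d
                dx_des += 0.5 * inertia * hx
                dy_des += 0.5 * inertia * hy
            elif i == follower and t >= lag:
                mx = my = 0.0
                for j in range(n_fish):
                    if j != i:
                        mx += head[t - lag, j, 0]
                        my += head[t - lag, j, 1]
                nm = np.sqrt(mx * mx + my * my)
                if nm > 1e-12:
                    dx_des = w_follow_t[t] * mx / nm
                    dy_des = w_follow_t[t] * my / nm
                dx_des += inertia_follow * hx
                dy_des += inertia_follow * hy
            else:
                if n_al > 0:
                    nm = np.sqrt(ax * ax + ay * ay)
                    if nm > 1e-12:
                        dx_des += w_align_t[t] * ax / nm
                        dy_des += w_align_t[t] * ay / nm
                if n_at > 0:
                    gx = cx / n_at - pos[t, i, 0]
                    gy = cy / n_at - pos[t, i, 1]
                    nm = np.sqrt(gx * gx + gy * gy)
                    if nm > 1e-12:
                        # spring-like pull saturating at the alignment radius,
                        # so the attraction weight sets the equilibrium spacing
                        pull = nm / r_align
                        if pull > 1.0:
                            pull = 1.0
                        dx_des += w_attr_t[t] * pull * gx / nm
                        dy_des += w_attr_t[t] * pull * gy / nm
                dx_des += inertia * hx
                dy_des += inertia * hy
            # wall avoidance: deflect toward the inward normal inside the buffer
            d_wall = 1e18
            k_wall = -1
            for k in range(normals.shape[0]):
                dk = wall_offsets[k] - (
                    pos[t, i, 0] * normals[k, 0] + pos[t, i, 1] * normals[k, 1]
                )
                if dk < d_wall:
                    d_wall = dk
                    k_wall = k
            if d_wall < wall_buffer:
                f = wall_weight * (1.0 - d_wall / wall_buffer)
                dx_des -= f * normals[k_wall, 0]
                dy_des -= f * normals[k_wall, 1]
            nm = np.sqrt(dx_des * dx_des + dy_des * dy_des)
            if nm < 1e-12:
                dx_des, dy_des = hx, hy
                nm = 1.0
            phi = np.arctan2(dy_des, dx_des) + sigma_t[t] * dphi[t, i]
            desired[i, 0] = np.cos(phi)
            desired[i, 1] = np.sin(phi)
        for i in range(n_fish):
            head[t + 1, i, 0] = desired[i, 0]
            head[t + 1, i, 1] = desired[i, 1]
            e[i] = speed_ar * e[i] + ar_innov * e_sd_t[t] * dspd[t, i]
            s = pref_t[t] + g_series[t] + offset[t, i] + e[i]
            if s < 0.0:
                s = 0.0
            px = pos[t, i, 0] + s * dt * desired[i, 0]
            py = pos[t, i, 1] + s * dt * desired[i, 1]
            # project back inside if the step crossed a wall
            for _ in range(2):
                for k in range(normals.shape[0]):
                    over = px * normals[k, 0] + py * normals[k, 1] - wall_offsets[k]
                    if over > -0.25:
                        px -= (over + 0.25) * normals[k, 0]
                        py -= (over + 0.25) * normals[k, 1]
            for k in range(normals.shape[0]):
                if px * normals[k, 0] + py * normals[k, 1] - wall_offsets[k] > 1.0:
                    escaped = 1
            pos[t + 1, i, 0] = px
            pos[t + 1, i, 1] = py
    return escaped


def simulate_trial(
    cfg: SimulationConfig,
    trial_id: str = "sim",
    treatment: str = "ambient",
) -> tuple[TrajectoryDataset, dict]:
    """Simulate one two-half trial; returns (dataset, ground-truth record).

    The disruption multipliers in ``cfg.disruption`` apply from the half
    boundary on.  Identical config (including seed) gives bit-identical
    output.
    """
    rng = np.random.default_rng(cfg.seed)
    H = cfg.half_frames
    burn = int(round(cfg.burn_in * cfg.fps))
    T = burn + 2 * H
    n = cfg.n_fish
    dt = 1.0 / cfg.fps
    d = cfg.disruption
    boundary = burn + H

    # per-step effective parameters (disruption applies in half 2)
    in_half2 = np.arange(T) >= boundary
    w_align_t = np.where(in_half2, cfg.w_alignment * d.alignment_mult, cfg.w_alignment)
    w_attr_t = np.where(in_half2, cfg.w_attraction * d.attraction_mult, cfg.w_attraction)
    sigma_t = np.where(in_half2, cfg.heading_noise * d.noise_mult, cfg.heading_noise)
    pref_t = np.where(in_half2, cfg.preferred_speed * d.speed_mult, cfg.preferred_speed)
    e_sd_t = np.where(in_half2, cfg.speed_noise * d.noise_mult, cfg.speed_noise)
    # the follower's copying strength degrades with the same alignment multiplier
    w_follow_t = np.where(
        in_half2, cfg.follower_weight * d.alignment_mult, cfg.follower_weight
    )

    def ar1(rho_ar: float, sd: float, shape) -> np.ndarray:
        x = np.empty((T,) + shape)
        x[0] = rng.normal(0.0, sd, shape)
        innov = rng.normal(0.0, sd * np.sqrt(1 - rho_ar**2), (T - 1,) + shape)
        for t in range(1, T):
            x[t] = rho_ar * x[t - 1] + innov[t - 1]
        return x

    # shared near-white speed fluctuation couples neighbours' speeds without
    # introducing slow group-level drift between halves
    g = ar1(cfg.group_speed_ar, cfg.group_speed_noise, ())
    # persistent individual speed offsets (slow AR, per-fish "personality")
    rho_slow = float(np.exp(-dt / cfg.indiv_speed_tau))
    offset = ar1(rho_slow, cfg.indiv_speed_sd, (n,))
    # slow shared cohesion state: the whole shoal drifts between tighter and
    # looser configurations (multiplies the attraction weight)
    if cfg.cohesion_drift_sd > 0:
        rho_c = float(np.exp(-dt / cfg.cohesion_drift_tau))
        w_attr_t = w_attr_t * np.exp(ar1(rho_c, cfg.cohesion_drift_sd, ()))

    rho = cfg.speed_ar
    dphi = rng.standard_normal((T, n))
    dspd = rng.standard_normal((T, n))
    e0 = rng.normal(0.0, cfg.speed_noise, n)

    pos = np.zeros((T, n, 2))
    head = np.zeros((T, n, 2))
    r0 = 12.0 * np.sqrt(rng.uniform(0.2, 1.0, n))
    th0 = rng.uniform(0, 2 * np.pi, n)
    pos[0, :, 0] = r0 * np.cos(th0)
    pos[0, :, 1] = r0 * np.sin(th0)
    phi0 = rng.uniform(0, 2 * np.pi) + rng.normal(0, 0.3, n)
    head[0, :, 0] = np.cos(phi0)
    head[0, :, 1] = np.sin(phi0)

    follower = n - 1
    escaped = _simulate_core(
        pos, head, T, n, dt,
        cfg.arena._normals, cfg.arena._offsets,
        cfg.r_repulsion, cfg.r_alignment, cfg.r_attraction,
        w_align_t.astype(float), w_attr_t.astype(float), sigma_t.astype(float),
        pref_t.astype(float), e_sd_t.astype(float),
        cfg.heading_inertia, cfg.wall_buffer, cfg.wall_weight,
        follower, cfg.follower_lag, w_follow_t.astype(float), cfg.follower_inertia,
        rho, g, offset, dphi, dspd, e0,
    )
    if escaped:
        raise RuntimeError("simulated fish escaped the arena (integration bug)")

    ds = TrajectoryDataset(
        trial_id=trial_id,
        positions=pos[burn:],
        frames=np.arange(2 * H),
        fish_ids=np.arange(n),
        fps=cfg.fps,
        arena=cfg.arena,
        half_boundary=H,
        treatment=treatment,
    )
    truth = {
        "trial_id": trial_id,
        "treatment": treatment,
        "seed": cfg.seed,
        "follower": follower,
        "follower_lag": cfg.follower_lag,
        "speed_mult": d.speed_mult,
        "alignment_mult": d.alignment_mult,
        "attraction_mult": d.attraction_mult,
        "noise_mult": d.noise_mult,
    }
    return ds, truth


def generate_experiment(
    n_groups_per_treatment: int = 15,
    ambient_spec: DisruptionSpec = DEFAULT_AMBIENT_SPEC,
    pile_spec: DisruptionSpec = DEFAULT_PILE_SPEC,
    base_cfg: Optional[SimulationConfig] = None,
    master_seed: int = 0,
) -> tuple[list[tuple[TrajectoryDataset, dict]], pd.DataFrame]:
    """Simulate a full playback experiment.

    2 x n groups, randomized complete block order: each consecutive pair of
    trials contains one trial of each treatment in random order.  Per-trial
    seeds are derived reproducibly from ``master_seed``.  Returns the list
    of (dataset, ground truth) and the design table.
    """
    if n_groups_per_treatment < 1:
        raise ValueError("need at least one group per treatment")
    if base_cfg is None:
        base_cfg = SimulationConfig()
    order_rng = np.random.default_rng(np.random.SeedSequence([int(master_seed), 0xB10C]))
    seeds = np.random.SeedSequence(int(master_seed)).generate_state(
        2 * n_groups_per_treatment
    ) % (2**31)
    trials = []
    records = []
    k = 0
    for block in range(n_groups_per_treatment):
        pair = ["ambient", "pile_driving"]
        if order_rng.random() < 0.5:
            pair.reverse()
        for treatment in pair:
            spec = ambient_spec if treatment == "ambient" else pile_spec
            cfg = replace(base_cfg, disruption=spec, seed=int(seeds[k]))
            trial_id = f"T{k + 1:02d}"
            ds, truth = simulate_trial(cfg, trial_id=trial_id, treatment=treatment)
            trials.append((ds, truth))
            truth = dict(truth, block=block + 1)
            records.append(truth)
            k += 1
    design = pd.DataFrame(records)
    return trials, design
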