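"""Plot helpers for the shoal metrics and model results."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import pandas as pd

from .metrics import RelativePositionMap

__all__ = ["plot_relative_position_map", "plot_half_comparison"]


def plot_relative_position_map(rp: RelativePositionMap, ax=None):
    """Heat map of where the nearest neighbour sits around the focal fish
    (focal at the origin, facing up the positive y-axis)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    extent = [rp.edges[0], rp.edges[-1], rp.edges[0], rp.edges[-1]]
    im = ax.imshow(rp.grid, origin="lower", extent=extent, cmap="inferno")
    ax.set_xlabel("right of focal fish (cm)")
    ax.set_ylabel("ahead of focal fish (cm)")
    ax.plot(0, 0, "w^", ms=8)
    plt.colorbar(im, ax=ax, label="probability")
    return ax


def plot_half_comparison(responses: pd.DataFrame, response: str, ax=None):
    """Box plots of a response by treatment and trial half."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    order = [
        ("ambient", "first"), ("ambient", "second"),
        ("pile_driving", "first"), ("pile_driving", "second"),
    ]
    data, labels, colors = [], [], []
    for treat, half in order:
        sel = responses[(responses.treatment == treat) & (responses.half == half)]
        data.append(sel[response].dropna().to_numpy())
        labels.append(f"{'amb' if treat == 'ambient' else 'pile'}\n{half}")
        colors.append("tab:blue" if treat == "ambient" else "tab:red")
    bp = ax.boxplot(data, tick_labels=labels, patch_artist=True)
    for patch, c in zip(bp["boxes"], colors):
        patch.set_facecolor(c)
        patch.set_alpha(0.5)
    ax.set_ylabel(response)
    return ax
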