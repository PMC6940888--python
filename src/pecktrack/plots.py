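"""Figures for the kinematics battery: per-order/per-feed boxplots of the
four kinematic variables and the catch-and-throw frequency bar chart."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .stats import KINEMATIC_VARIABLES, catch_and_throw_summary

LABELS = {
    "max_gape_mm": "Max. beak gape (mm)",
    "displacement_mm": "Head displacement (mm)",
    "duration_ms": "Time (ms)",
    "speed_mm_s": "Head av. speed (mm/s)",
}


def plot_kinematics_box(records: pd.DataFrame):
    """2x2 panel of boxplots: variable value vs mandibulation order, one box
    group per feed type."""
    feeds = sorted(records["feed_type"].unique())
    orders = sorted(records["order"].unique())
    fig, axes = plt.subplots(2, 2, figsize=(10, 7), constrained_layout=True)
    width = 0.8 / max(len(feeds), 1)
    for ax, var in zip(axes.ravel(), KINEMATIC_VARIABLES):
        for fi, feed in enumerate(feeds):
            data = [
                records.loc[
                    (records.feed_type == feed) & (records.order == o), var
                ].to_numpy()
                for o in orders
            ]
            pos = [o + (fi - (len(feeds) - 1) / 2) * width for o in orders]
            bp = ax.boxplot(
                data, positions=pos, widths=width * 0.85, patch_artist=True,
                showfliers=False,
            )
            color = f"C{fi}"
            for box in bp["boxes"]:
                box.set_facecolor(color)
                box.set_alpha(0.6)
        ax.set_xticks(orders)
        ax.set_xticklabels([str(o) for o in orders])
        ax.set_xlabel("Mandibulation order")
        ax.set_ylabel(LABELS.get(var, var))
    handles = [plt.Rectangle((0, 0), 1, 1, fc=f"C{i}", alpha=0.6) for i in range(len(feeds))]
    fig.legend(handles, feeds, loc="upper right")
    return fig


def plot_catch_and_throw(records: pd.DataFrame):
    """Catch-and-throw percentage per mandibulation order, grouped by feed."""
    summary = catch_and_throw_summary(records)["per_order_pct"]
    feeds = sorted(summary)
    orders = sorted({o for d in summary.values() for o in d})
    fig, ax = plt.subplots(figsize=(7, 4), constrained_layout=True)
    width = 0.8 / max(len(feeds), 1)
    for fi, feed in enumerate(feeds):
        vals = [summary[feed].get(o, 0.0) for o in orders]
        pos = [o + (fi - (len(feeds) - 1) / 2) * width for o in orders]
        ax.bar(pos, vals, width * 0.9, label=feed)
    ax.set_xticks(orders)
    ax.set_xlabel("Mandibulation order")
    ax.set_ylabel('"Catch-and-throw" (%)')
    ax.legend()
    return fig
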