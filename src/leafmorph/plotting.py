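"""Figure helpers: effect heatmaps, allometric panels, trajectory arrows.

Thin matplotlib wrappers over the analysis results; aesthetics are minimal
and every function returns the figure so callers can restyle or save.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .allometry import SUBREGIONS, AllometryResults, subarea_frame

_SUBREGION_COLORS = {
    "distal_blade": "#7fbf5f",  # light green
    "proximal_blade": "#2d6a2d",  # dark green
    "midvein": "#c8a165",  # light brown
    "proximal_vein": "#7a5230",  # dark brown
}


def effect_heatmap(table: pd.DataFrame, order: list[str] | None = None, ax=None):
    """Signed-magnitude heatmap of an effect table (traits x terms):
    magenta positive, green negative, opacity by magnitude."""
    if order is not None:
        table = table.loc[order]
    if ax is None:
        _, ax = plt.subplots(figsize=(0.18 * len(table) + 2, 0.3 * table.shape[1] + 2))
    vmax = np.nanmax(np.abs(table.to_numpy())) or 1.0
    ax.imshow(
        table.to_numpy().T, aspect="auto", cmap="PiYG_r", vmin=-vmax, vmax=vmax
    )
    ax.set_yticks(range(table.shape[1]), table.columns, fontsize=6)
    ax.set_xticks(range(len(table)), table.index, rotation=90, fontsize=5)
    return ax.figure


def allometry_panels(records, fits: AllometryResults, max_panels: int = 12):
    """Scatter of sqrt(subarea) vs sqrt(total) with fitted lines, one panel
    per group, colored by subregion."""
    df = subarea_frame(records)
    df = df[df["valid"]]
    groups = (
        {"overall": df}
        if fits.group_by == "overall"
        else dict(list(df.groupby("species"))[:max_panels])
    )
    n = len(groups)
    ncol = min(4, n)
    nrow = int(np.ceil(n / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 3.0 * nrow), squeeze=False)
    for ax, (gname, g) in zip(axes.ravel(), groups.items()):
        x = np.sqrt(g["area_total"])
        xs = np.linspace(x.min(), x.max(), 50)
        for sub in SUBREGIONS:
            color = _SUBREGION_COLORS[sub]
            ax.scatter(x, np.sqrt(g[f"area_{sub}"]), s=4, alpha=0.4, color=color)
            try:
                f = next(
                    f for f in fits.fits if f.group == str(gname) and f.subregion == sub
                )
            except StopIteration:
                continue
            ax.plot(xs, f.intercept + f.slope * xs, color=color, lw=1.2, label=sub)
        ax.set_title(str(gname), fontsize=8)
    for ax in axes.ravel()[n:]:
        ax.axis("off")
    axes[0, 0].legend(fontsize=6)
    fig.supxlabel("sqrt total area")
    fig.supylabel("sqrt subarea")
    fig.tight_layout()
    return fig


def trajectory_plot(embedding_df: pd.DataFrame, vectors, centered: bool = False):
    """Embedding scatter (colored by class) with per-vine arrows."""
    fig, ax = plt.subplots(figsize=(6, 6))
    classes = sorted(embedding_df["class_label"].dropna().unique())
    cmap = plt.get_cmap("tab10")
    color_of = {c: cmap(i % 10) for i, c in enumerate(classes)}
    if not centered:
        for c in classes:
            sel = embedding_df["class_label"] == c
            ax.scatter(
                embedding_df.loc[sel, "dim1"],
                embedding_df.loc[sel, "dim2"],
                s=6,
                alpha=0.4,
                color=color_of[c],
                label=f"class {c}",
            )
    for v in vectors:
        ax.annotate(
            "",
            xy=v.tip,
            xytext=v.base,
            arrowprops=dict(
                arrowstyle="->", color=color_of.get(v.class_label, "gray"), lw=1.0
            ),
        )
        if not centered:
            ax.plot(*v.base, "o", mfc="none", mec="black", ms=4)
    ax.set_xlabel("Dimension 1")
    ax.set_ylabel("Dimension 2")
    if classes:
        ax.legend(fontsize=7)
    return fig
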